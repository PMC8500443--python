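#!/usr/bin/env python
"""Generate the synthetic field/UAV campaign.

Writes, for each of the two seasons, the daily weather forcing, the 12
treatments' noisy UAV-style LAI observations (5 dates each), the measured
yields, and the truth-parameter sidecar, under results/campaign/.
"""

from pathlib import Path

from cropassim.pipeline import PipelineConfig, export_synthetic, read_observations

OUT = Path(__file__).resolve().parent.parent / "results" / "campaign"


def main() -> None:
    config = PipelineConfig(seasons=("2015-2016", "2016-2017"), seed=42, noise_cv=0.10)
    export_synthetic(config, OUT)
    for season in config.seasons:
        obs = read_observations(OUT / f"observations_{season}.csv")
        lai = [v for o in obs for v in o.lai_uav]
        print(
            f"{season}: {len(obs)} treatments x {len(obs[0])} observations, "
            f"LAI range {min(lai):.2f}-{max(lai):.2f}"
        )
    print(f"campaign written to {OUT}")


if __name__ == "__main__":
    main()
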