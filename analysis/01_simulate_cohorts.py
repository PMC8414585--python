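"""Materialize the synthetic GWAS fixtures used by the downstream analyses.

Writes one directory of delimited summary statistics (exposure, outcome, LD
matrix, truth manifest) per named scenario, plus six bidirectional study
directories shaped like the biomarker <-> disease design: three forward
(biomarker -> disease, binary outcome) and three reverse (disease liability
-> biomarker, continuous outcome).
"""

import dataclasses
from pathlib import Path

from mrkit import SCENARIOS, simulate_study, write_study

RESULTS = Path(__file__).resolve().parents[1] / "results"
FIXTURES = RESULTS / "fixtures"

BIDIRECTIONAL = {
    # name -> (direction, causal log-OR per SD or SD per log-OR, seed)
    "gdf15_to_ad": ("forward", 0.131, 101),   # ln(1.14): the positive finding
    "gdf15_to_pd": ("forward", 0.0, 102),
    "gdf15_to_als": ("forward", 0.0, 103),
    "ad_to_gdf15": ("reverse", 0.0, 104),
    "pd_to_gdf15": ("reverse", 0.0, 105),
    "als_to_gdf15": ("reverse", 0.0, 106),
}


def main() -> None:
    for name, config in SCENARIOS.items():
        outdir = FIXTURES / "scenarios" / name
        write_study(simulate_study(config), outdir)
        print(f"scenario {name}: wrote {outdir}")

    base = SCENARIOS["null"]
    for name, (direction, beta, seed) in BIDIRECTIONAL.items():
        config = dataclasses.replace(base, causal_beta=beta, seed=seed)
        outdir = FIXTURES / "bidirectional" / name
        write_study(simulate_study(config), outdir)
        print(f"pair {name} ({direction}, true effect {beta}): wrote {outdir}")


if __name__ == "__main__":
    main()
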