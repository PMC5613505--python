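#!/usr/bin/env python
"""Map the generator's complexity knob onto fragment ApEn.

The synthetic cohorts encode subject "complexity" as the noise-mixing
fraction c of each band process.  This script traces ApEn of a 15-s β2
fragment as a function of c, which is what justifies the cohort
defaults: the response is roughly linear in ln c up to c ≈ 0.3 and
saturates above ≈ 0.5, so a moderate-group base of 0.18 with a 0.6
log-normal spread lands near the published moderate summaries
(mean ≈ 0.54, wide SD) while the marked group's base of 0.65 sits on
the saturated shelf (mean ≈ 0.60, narrow SD).

Writes results/complexity_response.csv and prints the table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from emoeeg import CohortSpec, approximate_entropy, design_paper_timeline, generate_cohort
from emoeeg.preprocess import rereference, segment, DEFAULT_BANDS

OUT = Path(__file__).resolve().parents[1] / "results"


def response_curve(band_name="beta2", reps=6):
    rows = []
    band = next(b for b in DEFAULT_BANDS if b.name == band_name)
    for c in (0.0, 0.01, 0.02, 0.05, 0.1, 0.18, 0.3, 0.5, 0.65, 0.8, 1.0):
        vals = []
        for rep in range(reps):
            spec = CohortSpec(
                n_normal=0, n_moderate=1, n_marked=0, seed=1000 + rep,
                electrodes=("Fz", "A1", "A2"),
                complexity_base={b.name: c for b in DEFAULT_BANDS},
                beta_effect=0.0, complexity_sd=0.0, band_jitter_sd=0.0,
            )
            cohort = generate_cohort(spec)
            frags = segment(rereference(cohort.recordings[0]), design_paper_timeline(),
                            bands=(band,))
            vals.append(np.mean([approximate_entropy(f.samples).value for f in frags[:3]]))
        rows.append({"c": c, "apen_mean": np.mean(vals), "apen_sd": np.std(vals, ddof=1)})
    return pd.DataFrame(rows)


def main():
    OUT.mkdir(exist_ok=True)
    curve = response_curve()
    curve.to_csv(OUT / "complexity_response.csv", index=False, float_format="%.4f")
    print("ApEn response of a β2 Fz fragment to the noise-mixing fraction c:")
    print(curve.round(4).to_string(index=False))
    print(
        "\nThe knee of the curve motivates the cohort defaults: moderate base "
        "c=0.18 (steep region, wide entropy spread under log-normal jitter), "
        "marked base c=0.65 (saturated shelf, narrow spread)."
    )


if __name__ == "__main__":
    sys.exit(main())
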