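"""Published reference values from the motivating clinical study.

The raw patient recordings behind the original emotion-evoked EEG study
of schizophrenia severity were never deposited, but its printed
group-level summaries are themselves re-analysable data.  This module
stores them:

* ``FZ_APEN_BETA_SUMMARY`` — per β-band × emotion × section cell, the
  moderately-ill and markedly-ill groups' mean (SD) of the Fz ApEn
  feature (n = 17 each) together with the published pooled-variance t.
  Feeding the means/SDs to :func:`emoeeg.stats.t_from_summary`
  reproduces the published t values to within the uncertainty induced
  by their 3-decimal rounding.
* ``PANSS_GROUP_PARAMS`` — the two patient groups' PANSS-total mean/SD,
  which the synthetic-cohort generator adopts as its defaults.
* ``REFERENCE_BETA_CORRELATION`` — the typical published Pearson
  correlation between the β2 Fz ApEn feature and the PANSS total
  (≈ 0.55), the generator's default correlation target.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["CellSummary", "FZ_APEN_BETA_SUMMARY", "PANSS_GROUP_PARAMS", "REFERENCE_BETA_CORRELATION"]


class CellSummary(NamedTuple):
    mean_moderate: float
    sd_moderate: float
    mean_marked: float
    sd_marked: float
    t_published: float
    n_per_group: int = 17


# (band, emotion, section) -> published group summaries of Fz ApEn
FZ_APEN_BETA_SUMMARY: dict[tuple[str, str, int], CellSummary] = {
    ("beta1", "HVLA", 1): CellSummary(0.583, 0.069, 0.625, 0.009, -2.462),
    ("beta1", "HVLA", 2): CellSummary(0.597, 0.040, 0.624, 0.006, -2.801),
    ("beta1", "HVLA", 3): CellSummary(0.589, 0.048, 0.627, 0.005, -3.231),
    ("beta1", "LVLA", 1): CellSummary(0.587, 0.055, 0.626, 0.005, -2.860),
    ("beta1", "LVLA", 2): CellSummary(0.587, 0.042, 0.627, 0.004, -3.999),
    ("beta1", "LVLA", 3): CellSummary(0.590, 0.043, 0.627, 0.005, -3.616),
    ("beta1", "LVHA", 1): CellSummary(0.588, 0.050, 0.621, 0.025, -2.417),
    ("beta1", "LVHA", 2): CellSummary(0.587, 0.046, 0.624, 0.016, -3.126),
    ("beta1", "LVHA", 3): CellSummary(0.573, 0.062, 0.622, 0.018, -3.086),
    ("beta2", "HVLA", 1): CellSummary(0.538, 0.071, 0.608, 0.013, -4.050),
    ("beta2", "HVLA", 2): CellSummary(0.543, 0.067, 0.606, 0.012, -3.812),
    ("beta2", "HVLA", 3): CellSummary(0.540, 0.067, 0.609, 0.008, -4.214),
    ("beta2", "LVLA", 1): CellSummary(0.538, 0.064, 0.606, 0.006, -4.325),
    ("beta2", "LVLA", 2): CellSummary(0.540, 0.067, 0.606, 0.013, -3.957),
    ("beta2", "LVLA", 3): CellSummary(0.540, 0.065, 0.605, 0.011, -4.014),
    ("beta2", "LVHA", 1): CellSummary(0.537, 0.064, 0.602, 0.016, -4.047),
    ("beta2", "LVHA", 2): CellSummary(0.536, 0.067, 0.605, 0.021, -4.052),
    ("beta2", "LVHA", 3): CellSummary(0.537, 0.066, 0.607, 0.014, -4.276),
    ("beta3", "HVLA", 1): CellSummary(0.564, 0.051, 0.554, 0.015, 0.788),
    ("beta3", "HVLA", 2): CellSummary(0.575, 0.044, 0.555, 0.015, 1.735),
    ("beta3", "HVLA", 3): CellSummary(0.568, 0.043, 0.557, 0.015, 1.041),
    ("beta3", "LVLA", 1): CellSummary(0.569, 0.047, 0.554, 0.014, 1.275),
    ("beta3", "LVLA", 2): CellSummary(0.567, 0.045, 0.558, 0.012, 0.821),
    ("beta3", "LVLA", 3): CellSummary(0.570, 0.045, 0.555, 0.013, 1.381),
    ("beta3", "LVHA", 1): CellSummary(0.568, 0.046, 0.556, 0.019, 0.960),
    ("beta3", "LVHA", 2): CellSummary(0.573, 0.045, 0.554, 0.018, 1.581),
    ("beta3", "LVHA", 3): CellSummary(0.563, 0.051, 0.552, 0.014, 0.897),
}

# PANSS-total (mean, SD) per patient group, n = 17 each
PANSS_GROUP_PARAMS = {
    "moderately_ill": (70.06, 4.25),
    "markedly_ill": (95.88, 10.53),
}

REFERENCE_BETA_CORRELATION = 0.55
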