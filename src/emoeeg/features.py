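"""Entropy feature extraction: fragments → subject × condition table.

A :class:`FeatureTable` holds one row per subject and one column per
(electrode, method, emotion, band, section) cell.  With the default
protocol — 3 scalp electrodes, 3 entropy methods, 3 emotion categories,
5 bands, 3 sections — that is 405 columns.  The 15-column sub-table of
one (electrode, method, emotion) cell (5 bands × 3 sections) is the
feature matrix handed to the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .entropy_core import (
    ApEnConfig,
    OrdinalConfig,
    amplitude_aware_permutation_entropy,
    approximate_entropy,
    permutation_entropy,
)
from .preprocess import Fragment

__all__ = ["METHODS", "FeatureTable", "MissingCellError", "compute_features", "select_cell"]

METHODS = ("ApEn", "PE", "AAPE")
_LEVELS = ("electrode", "method", "emotion", "band", "section")


class MissingCellError(ValueError):
    """A subject's fragment set does not cover the full condition grid."""

    def __init__(self, gaps: dict[str, list[tuple]]):
        self.gaps = gaps
        lines = "; ".join(f"{subj}: {cells[:5]}" for subj, cells in gaps.items())
        super().__init__(f"incomplete feature grid — missing cells: {lines}")


@dataclass
class FeatureTable:
    """Subject × (electrode, method, emotion, band, section) entropy values."""

    data: pd.DataFrame  # MultiIndex columns with levels _LEVELS
    apen_config: ApEnConfig = field(default_factory=ApEnConfig)
    ordinal_config: OrdinalConfig = field(default_factory=OrdinalConfig)

    def __post_init__(self) -> None:
        # lexically sorted columns make cell lookups unambiguous and fast
        self.data = self.data.sort_index(axis=1)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def select_cell(
        self, electrode: str, method: str, emotion: str, pool_sections: bool = False
    ) -> pd.DataFrame:
        """Feature matrix of one classification condition.

        Returns subjects × (band, section) — 15 columns with defaults —
        or subjects × band (5 columns, section-averaged) when
        ``pool_sections`` is set.
        """
        key = (electrode, method, emotion)
        for level, val in zip(_LEVELS[:3], key):
            if val not in self.data.columns.get_level_values(level):
                raise KeyError(f"{level} {val!r} not present in the feature table")
        sub = self.data.loc[:, key]  # columns: (band, section)
        sub = sub.sort_index(axis=1)
        if pool_sections:
            sub = sub.T.groupby(level="band").mean().T
        return sub

    # --- round-trip -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table with systematic ``elec.method.emotion.band.sec``
        column names plus a JSON sidecar carrying the entropy configs."""
        path = Path(path)
        flat = self.data.copy()
        flat.columns = [".".join(str(p) for p in col) for col in self.data.columns]
        flat.index.name = "subject_id"
        flat.to_csv(path, float_format="%.17g")
        sidecar = {
            "apen_config": self.apen_config.__dict__,
            "ordinal_config": self.ordinal_config.__dict__,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        flat = pd.read_csv(path, index_col="subject_id")
        cols = []
        for name in flat.columns:
            electrode, method, emotion, band, section = name.split(".")
            cols.append((electrode, method, emotion, band, int(section)))
        flat.columns = pd.MultiIndex.from_tuples(cols, names=_LEVELS)
        sidecar_path = path.with_suffix(".json")
        apen_cfg, ord_cfg = ApEnConfig(), OrdinalConfig()
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            apen_cfg = ApEnConfig(**sidecar["apen_config"])
            ord_cfg = OrdinalConfig(**sidecar["ordinal_config"])
        return cls(flat, apen_cfg, ord_cfg)


def _entropy_of(fragment: Fragment, method: str, apen_config, ordinal_config) -> float:
    x = fragment.samples
    if method == "ApEn":
        return approximate_entropy(x, apen_config).value
    if method == "PE":
        return permutation_entropy(x, ordinal_config).value
    if method == "AAPE":
        return amplitude_aware_permutation_entropy(x, ordinal_config).value
    raise ValueError(f"unknown entropy method {method!r}")


def compute_features(
    fragments: Iterable[Fragment],
    methods: Sequence[str] = METHODS,
    apen_config: ApEnConfig | None = None,
    ordinal_config: OrdinalConfig | None = None,
) -> FeatureTable:
    """One entropy value per fragment per method, assembled per subject.

    The condition grid (electrode × emotion × band × section) is taken as
    the union over all subjects; any subject lacking a cell raises
    :class:`MissingCellError` naming the gaps.  The SD-relative ApEn
    tolerance is resolved per fragment.
    """
    apen_config = apen_config or ApEnConfig()
    ordinal_config = ordinal_config or OrdinalConfig()
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown entropy method {m!r}")

    per_subject: dict[str, dict[tuple, float]] = {}
    for frag in fragments:
        row = per_subject.setdefault(frag.subject_id, {})
        for method in methods:
            key = (frag.electrode, method, frag.emotion, frag.band, frag.section)
            row[key] = _entropy_of(frag, method, apen_config, ordinal_config)

    grid = sorted({k for row in per_subject.values() for k in row})
    gaps = {
        subj: sorted(set(grid) - set(row))
        for subj, row in per_subject.items()
        if set(row) != set(grid)
    }
    if gaps:
        raise MissingCellError(gaps)

    columns = pd.MultiIndex.from_tuples(grid, names=_LEVELS)
    data = pd.DataFrame(
        [[per_subject[s][k] for k in grid] for s in per_subject],
        index=pd.Index(list(per_subject), name="subject_id"),
        columns=columns,
    )
    return FeatureTable(data, apen_config, ordinal_config)


def select_cell(
    table: FeatureTable, electrode: str, method: str, emotion: str, **kwargs
) -> pd.DataFrame:
    """Module-level alias of :meth:`FeatureTable.select_cell`."""
    return table.select_cell(electrode, method, emotion, **kwargs)
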