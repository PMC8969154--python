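"""Label-free acyl-site quantification.

Stages: per-sample protein abundance from unmodified peptides, division of
every acyl-peptide intensity by that abundance, low-abundance resampling of
missing values, per-site log2 fold change + Student t between a condition
pair, residue-coordinate mapping onto the full-length protein, and
modification-mass arithmetic from elemental compositions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidConfigError,
    NormalizationError,
    UnimputableSampleError,
    CoordinateError,
)

__all__ = [
    "TABLE_COLUMNS",
    "MONOISOTOPIC_MASS",
    "ModComposition",
    "SiteQuantResult",
    "validate_table",
    "protein_abundance",
    "normalize",
    "impute_low",
    "site_differential",
    "map_residue",
    "unmap_residue",
    "mod_mass",
]

TABLE_COLUMNS = [
    "peptide_seq",
    "site_residue",
    "mod_type",
    "condition",
    "replicate",
    "intensity",
]

#: standard monoisotopic atomic masses, Da (CODATA/IUPAC)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
}

DEFAULT_LFC_THRESHOLD = 1.8
DEFAULT_ALPHA = 0.05


@dataclass
class ModComposition:
    """Elemental composition of an acyl modification and its mass shift."""

    mod_type: str
    formula: dict[str, int]

    @property
    def monoisotopic_mass(self) -> float:
        return mod_mass(self.formula)


@dataclass
class SiteQuantResult:
    site_residue: int
    condition_pair: tuple[str, str]
    log2fc: float
    p: float
    significant: bool
    testable: bool
    ratio_kind: Literal["glutarylation", "deglutarylation"] = "glutarylation"


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format quant table invariants; returns the table."""
    missing_cols = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise InvalidConfigError(f"quant table missing columns {missing_cols}")
    unmod = table["mod_type"] == "none"
    if table.loc[unmod, "site_residue"].notna().any():
        raise InvalidConfigError("unmodified rows must have null site_residue")
    if table.loc[~unmod, "site_residue"].isna().any():
        raise InvalidConfigError("modified rows must carry a site_residue")
    present = table["intensity"].dropna()
    if (present <= 0).any():
        raise InvalidConfigError("intensities must be positive where present")
    return table


def _samples(table: pd.DataFrame) -> list[tuple[str, int]]:
    return sorted(
        set(zip(table["condition"], table["replicate"])), key=lambda s: (str(s[0]), s[1])
    )


def protein_abundance(
    table: pd.DataFrame,
    sample: tuple[str, int],
    agg: Literal["mean", "median", "sum"] = "mean",
) -> float:
    """Protein-level abundance of one sample from unmodified peptides only."""
    condition, replicate = sample
    mask = (
        (table["condition"] == condition)
        & (table["replicate"] == replicate)
        & (table["mod_type"] == "none")
        & table["intensity"].notna()
    )
    values = table.loc[mask, "intensity"]
    if values.empty:
        raise NormalizationError(
            f"no unmodified peptide intensity in sample {sample}; cannot normalize"
        )
    if agg not in ("mean", "median", "sum"):
        raise InvalidConfigError(f"unknown aggregation {agg!r}")
    return float(getattr(values, agg)())


def normalize(
    table: pd.DataFrame, agg: Literal["mean", "median", "sum"] = "mean"
) -> pd.DataFrame:
    """Divide every intensity by its sample's protein-level abundance.

    Controls for sample-loading and instrument-performance drift: a global
    per-sample scale factor cancels exactly.
    """
    validate_table(table)
    out = table.copy()
    for sample in _samples(table):
        scale = protein_abundance(table, sample, agg=agg)
        mask = (out["condition"] == sample[0]) & (out["replicate"] == sample[1])
        out.loc[mask, "intensity"] = out.loc[mask, "intensity"] / scale
    return out


def impute_low(
    table: pd.DataFrame, quantile: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Fill missing intensities by resampling each sample's low-abundance tail.

    Each missing cell draws uniformly from that sample's observed intensities
    at or below its ``quantile`` intensity quantile; deterministic per seed.
    """
    if not 0 < quantile < 1:
        raise InvalidConfigError("quantile must lie in (0, 1)")
    frac_missing = table["intensity"].isna().mean()
    if frac_missing >= 0.5:
        raise InvalidConfigError(
            f"{frac_missing:.0%} of intensities missing; imputation requires <50%"
        )
    rng = np.random.default_rng(seed)
    out = table.copy()
    for sample in _samples(table):
        mask = (out["condition"] == sample[0]) & (out["replicate"] == sample[1])
        observed = out.loc[mask, "intensity"].dropna().to_numpy(float)
        holes = mask & out["intensity"].isna()
        n_holes = int(holes.sum())
        if n_holes == 0:
            continue
        if observed.size == 0:
            raise UnimputableSampleError(
                f"sample {sample} has no observed intensities to resample"
            )
        ceiling = np.quantile(observed, quantile)
        tail = observed[observed <= ceiling]
        if tail.size == 0:  # quantile below the minimum cannot happen, but guard
            tail = observed[observed == observed.min()]
        out.loc[holes, "intensity"] = rng.choice(tail, size=n_holes, replace=True)
    return out


def _site_sample_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average normalized intensities per (site, condition, replicate).

    Multiple peptides covering one site are averaged per sample before any
    statistics.
    """
    modified = table[table["mod_type"] != "none"]
    return (
        modified.groupby(["site_residue", "condition", "replicate"])["intensity"]
        .mean()
        .reset_index()
    )


def site_differential(
    normalized: pd.DataFrame,
    pair: tuple[str, str],
    n_reps: int = 3,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    ratio_kind: Literal["glutarylation", "deglutarylation"] = "glutarylation",
) -> list[SiteQuantResult]:
    """Per-site log2 fold change (B over A) with a pooled-variance Student t.

    log2fc = mean(log2 B) - mean(log2 A) of the site's normalized, per-sample
    averaged intensities; p is two-sided with df = 2n - 2.

    Significance: for ``ratio_kind="glutarylation"`` (modified over
    unmodified) the call requires log2fc > lfc_threshold AND p <= alpha;
    for ``ratio_kind="deglutarylation"`` (modified+eraser over modified)
    there is no fold-change gate and p <= alpha alone decides.
    Sites with zero variance in both groups are flagged not testable.
    """
    a_label, b_label = pair
    per_sample = _site_sample_means(normalized)
    if per_sample["intensity"].isna().any():
        raise InvalidConfigError("differential requires a complete (imputed) table")
    results = []
    for site, sub in per_sample.groupby("site_residue", sort=True):
        a = np.log2(sub.loc[sub["condition"] == a_label, "intensity"].to_numpy(float))
        b = np.log2(sub.loc[sub["condition"] == b_label, "intensity"].to_numpy(float))
        if a.size != n_reps or b.size != n_reps:
            raise InvalidConfigError(
                f"site {site}: expected {n_reps} replicates per condition, "
                f"got {a.size} vs {b.size}"
            )
        log2fc = float(b.mean() - a.mean())
        sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
        if sa2 == 0.0 and sb2 == 0.0:
            p = float("nan")
            testable = False
        else:
            df = a.size + b.size - 2
            sp2 = ((a.size - 1) * sa2 + (b.size - 1) * sb2) / df
            t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
            p = float(2.0 * stats.t.sf(abs(t), df))
            testable = True
        if ratio_kind == "glutarylation":
            significant = bool(testable and log2fc > lfc_threshold and p <= alpha)
        else:
            significant = bool(testable and p <= alpha)
        results.append(
            SiteQuantResult(
                site_residue=int(site),
                condition_pair=pair,
                log2fc=log2fc,
                p=p,
                significant=significant,
                testable=testable,
                ratio_kind=ratio_kind,
            )
        )
    return results


def map_residue(
    peptide_start_in_construct: int,
    offset_to_fulllength: int,
    within_peptide_pos: int,
) -> int:
    """Map a construct-local residue to the full-length protein coordinate.

    All positions are 1-based: full-length position = (peptide start in the
    construct) + (within-peptide position - 1) + (construct-to-full-length
    offset, e.g. a removed targeting presequence).
    """
    if offset_to_fulllength < 0:
        raise CoordinateError("offset must be non-negative")
    if peptide_start_in_construct < 1 or within_peptide_pos < 1:
        raise CoordinateError("positions are 1-based and must be >= 1")
    pos = peptide_start_in_construct + (within_peptide_pos - 1) + offset_to_fulllength
    if pos < 1:
        raise CoordinateError(f"mapped position {pos} is non-positive")
    return pos


def unmap_residue(fulllength_pos: int, offset_to_fulllength: int) -> int:
    """Inverse of :func:`map_residue` for a peptide starting at position 1."""
    pos = fulllength_pos - offset_to_fulllength
    if pos < 1:
        raise CoordinateError(f"construct position {pos} is non-positive")
    return pos


def mod_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass shift (Da) of an elemental composition.

    Limited to C, H, N, O, S — the elements of acyl modifications.
    """
    mass = 0.0
    for element, count in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise InvalidConfigError(f"unknown element {element!r}")
        if count < 0:
            raise InvalidConfigError("element counts must be non-negative")
        mass += count * MONOISOTOPIC_MASS[element]
    return mass


#: glutaryl and succinyl lysine mass shifts from their compositions
GLUTARYL = ModComposition("glutaryl", {"C": 5, "H": 6, "O": 3})
SUCCINYL = ModComposition("succinyl", {"C": 4, "H": 4, "O": 3})
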