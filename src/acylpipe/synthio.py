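"""Synthetic-data generators with emitted ground truth.

Every generator is seed-deterministic and returns (data, truth) so each
downstream stage can be scored without reading generator internals:

* expression matrices with a planted coexpression module around a query gene
  (single latent factor; closed-form target correlation),
* long-format acyl-peptide tables with per-sample loading factors and
  intensity-dependent missingness,
* van't Hoff two-state melting curves with linear baselines,
* linear initial-rate absorbance decays,
* group-structured metabolite peak-area tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .assay_quant import ActivityTrace
from .biophys import MeltingCurve, two_state_signal
from .coexpr import ExpressionMatrix
from .errors import InvalidConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_expression",
    "gen_acyl_table",
    "gen_melting_curve",
    "gen_activity_trace",
    "gen_metabolite_table",
]

#: global mean shift (in units of noise_sd) applied to tumor samples so the
#: non-tumor filter has an observable effect
TUMOR_SHIFT_SD = 0.5


@dataclass
class SimConfig:
    """Parameters of the expression-matrix generator."""

    seed: int
    n_genes: int = 2000
    n_samples: int = 200
    frac_tumor: float = 0.0
    planted_module_size: int = 20
    planted_r: float = 0.8
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 3:
            raise InvalidConfigError("need n_genes >= 2 and n_samples >= 3")
        if not 0 <= self.frac_tumor <= 1:
            raise InvalidConfigError("frac_tumor must lie in [0, 1]")
        if self.planted_module_size >= self.n_genes:
            raise InvalidConfigError("planted_module_size must be < n_genes")
        if self.planted_module_size < 0:
            raise InvalidConfigError("planted_module_size must be >= 0")
        if not 0 <= self.planted_r < 1:
            raise InvalidConfigError("planted_r must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Truth emitted alongside generated data, never embedded in it."""

    planted_gene_ids: set[str] = field(default_factory=set)
    true_site_log2fc: dict[int, float] = field(default_factory=dict)
    true_tm_by_curve: dict[str, float] = field(default_factory=dict)
    true_group_effects: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_gene_ids": sorted(self.planted_gene_ids),
            "true_site_log2fc": {str(k): v for k, v in self.true_site_log2fc.items()},
            "true_tm_by_curve": dict(self.true_tm_by_curve),
            "true_group_effects": dict(self.true_group_effects),
        }


def gen_expression(
    config: SimConfig, query_gene: str = "QUERY"
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-scale expression with a planted module correlated to a query gene.

    The query gene and the planted module genes share one latent factor:
    x = sqrt(r)*f + sqrt(1-r)*eps (then scaled by noise_sd), so the
    population correlation of every planted gene with the query is exactly
    ``planted_r``. All other genes are independent Gaussian noise. Tumor
    samples receive a +0.5*noise_sd global mean shift. Values are emitted
    already normalized on a log scale (recorded in the metadata).
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples

    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    gene_ids[0] = query_gene
    sample_ids = [f"S{i:04d}" for i in range(n_s)]

    n_tumor = int(round(config.frac_tumor * n_s))
    tumor = np.zeros(n_s, dtype=bool)
    tumor[rng.permutation(n_s)[:n_tumor]] = True

    x = rng.standard_normal((n_g, n_s))
    factor = rng.standard_normal(n_s)
    r = config.planted_r
    module_rows = np.arange(0, config.planted_module_size + 1)  # row 0 = query
    x[module_rows] = np.sqrt(r) * factor + np.sqrt(1.0 - r) * x[module_rows]
    x *= config.noise_sd
    x[:, tumor] += TUMOR_SHIFT_SD * config.noise_sd

    values = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {"tumor": tumor},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta.attrs["normalization"] = "already-normalized log-scale expression"
    truth = GroundTruth(planted_gene_ids=set(gene_ids[1 : config.planted_module_size + 1]))
    return ExpressionMatrix(values=values, sample_meta=meta), truth


def _missing_mask(
    log2_intensity: np.ndarray, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Intensity-dependent (logistic in log-intensity) missingness mask.

    P(missing) = expit(a - b*z) with z the standardized log2 intensity and a
    solved so the expected missing fraction equals ``missing_rate``.
    """
    if missing_rate == 0:
        return np.zeros_like(log2_intensity, dtype=bool)
    z = (log2_intensity - log2_intensity.mean()) / max(log2_intensity.std(), 1e-12)
    b = 2.0
    a = brentq(lambda a_: expit(a_ - b * z).mean() - missing_rate, -60.0, 60.0)
    return rng.random(log2_intensity.shape) < expit(a - b * z)


def gen_acyl_table(
    n_sites: int,
    n_unmod_peptides: int,
    conditions: list[str],
    n_reps: int,
    effect_log2fc: dict[int, float],
    missing_rate: float = 0.0,
    seed: int = 0,
    mod_type: str = "glutaryl",
    rep_noise_sd: float = 0.25,
    sample_scale_sd: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format peptide table with per-sample loading factors.

    Per-peptide log2 base levels are Gaussian (so intensities are
    log-normal); a per-sample log2 scale factor multiplies every peptide of
    that sample, making protein-level normalization necessary. Site effects
    in ``effect_log2fc`` are added in every condition after the first
    (``conditions[0]`` is the reference). Missing cells are placed
    preferentially at low intensity.
    """
    if not conditions:
        raise InvalidConfigError("conditions must be non-empty")
    if n_reps < 2:
        raise InvalidConfigError("need n_reps >= 2")
    if not 0 <= missing_rate < 0.5:
        raise InvalidConfigError("missing_rate must lie in [0, 0.5)")
    unknown = set(effect_log2fc) - set(range(1, n_sites + 1))
    if unknown:
        raise InvalidConfigError(f"effect sites outside 1..{n_sites}: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sites = [10 * (i + 1) + 3 for i in range(n_sites)]  # arbitrary K positions
    site_effect = {sites[i]: float(effect_log2fc.get(i + 1, 0.0)) for i in range(n_sites)}

    peptides = []
    for j in range(n_unmod_peptides):
        peptides.append((f"UNMOD_PEP_{j+1:02d}", None, "none"))
    for s in sites:
        peptides.append((f"K{s}_PEP", s, mod_type))

    base = rng.normal(20.0, 1.5, size=len(peptides))
    rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(1, n_reps + 1):
            scale = rng.normal(0.0, sample_scale_sd)
            noise = rng.normal(0.0, rep_noise_sd, size=len(peptides))
            for k, (pep, site, mt) in enumerate(peptides):
                lvl = base[k] + scale + noise[k]
                if site is not None and ci > 0:
                    lvl += site_effect[site]
                rows.append((pep, site, mt, cond, rep, lvl))
    table = pd.DataFrame(rows, columns=[
        "peptide_seq", "site_residue", "mod_type", "condition", "replicate", "intensity",
    ])
    log2_int = table["intensity"].to_numpy(float)
    mask = _missing_mask(log2_int, missing_rate, rng)
    table["intensity"] = np.power(2.0, log2_int)
    table.loc[mask, "intensity"] = np.nan
    table["site_residue"] = table["site_residue"].astype("Int64")

    truth = GroundTruth(true_site_log2fc={s: site_effect[s] for s in sites})
    return table, truth


def gen_melting_curve(
    tm_c: float,
    dh_vh: float = 300.0,
    baselines: tuple[float, float, float, float] = (-20.0, 0.02, -4.0, 0.01),
    noise_sd: float = 0.0,
    t_range: tuple[float, float] = (20.0, 85.0),
    step: float = 1.0,
    seed: int = 0,
    label: str = "",
) -> tuple[MeltingCurve, GroundTruth]:
    """Two-state melting curve with linear baselines and Gaussian signal noise.

    ``baselines`` is (yN, mN, yU, mU). Noise is added in raw signal units —
    the instrument measures raw ellipticity, not fraction unfolded.
    """
    lo, hi = t_range
    if step <= 0:
        raise InvalidConfigError("temperature step must be positive")
    if not lo <= tm_c <= hi:
        raise InvalidConfigError(f"tm_c must lie within t_range {t_range}")
    if dh_vh <= 0:
        raise InvalidConfigError("dh_vh must be positive")
    rng = np.random.default_rng(seed)
    temp = np.arange(lo, hi + step / 2, step)
    yN, mN, yU, mU = baselines
    signal = two_state_signal(temp, tm_c, dh_vh, yN, mN, yU, mU)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=temp.size)
    curve = MeltingCurve(temp_c=temp, signal=signal, label=label or f"tm{tm_c:g}")
    truth = GroundTruth(true_tm_by_curve={curve.label: float(tm_c)})
    return curve, truth


def gen_activity_trace(
    rate_nmol_min: float,
    dcpip0_uM: float = 30.0,
    eps_mM_cm: float = 21.0,
    path_cm: float = 1.0,
    volume_ml: float = 1.0,
    duration_s: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ActivityTrace:
    """Linear dye-reduction absorbance decay at a known true rate.

    A600(0) = eps*l*[dye]/1000; the slope is -eps*l*rate/(1000*volume) per
    minute. Raises if the dye would be exhausted within ``duration_s``.
    """
    if rate_nmol_min < 0:
        raise InvalidConfigError("rate must be non-negative")
    if dcpip0_uM <= 0 or duration_s < 3:
        raise InvalidConfigError("need positive dye concentration and >=3 s duration")
    dye_nmol = dcpip0_uM * volume_ml  # uM * mL = nmol
    if rate_nmol_min * duration_s / 60.0 >= dye_nmol:
        raise InvalidConfigError(
            "rate would exhaust the dye within the trace; shorten duration"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration_s + 1, dtype=float)
    a0 = eps_mM_cm * path_cm * dcpip0_uM / 1000.0
    slope_per_s = -eps_mM_cm * path_cm * rate_nmol_min / (1000.0 * volume_ml) / 60.0
    a = a0 + slope_per_s * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.size)
    return ActivityTrace(
        time_s=t, a600=a, eps_mM_cm=eps_mM_cm, path_cm=path_cm,
        volume_ml=volume_ml, label=label,
    )


def gen_metabolite_table(
    n_metabolites: int,
    groups: list[str],
    n_reps: int,
    effects: dict[str, float],
    seed: int = 0,
    rep_noise_sd: float = 0.15,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Log-normal metabolite peak areas with group mean shifts.

    ``effects`` maps metabolite id ("M0001", ...) to a log2 shift applied in
    every group after the first (``groups[0]`` is the reference).
    """
    if not groups:
        raise InvalidConfigError("groups must be non-empty")
    if n_reps < 2:
        raise InvalidConfigError("need n_reps >= 2")
    ids = [f"M{i:04d}" for i in range(1, n_metabolites + 1)]
    unknown = set(effects) - set(ids)
    if unknown:
        raise InvalidConfigError(f"effects for unknown metabolites: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = rng.normal(20.0, 1.5, size=n_metabolites)
    rows = []
    for gi, group in enumerate(groups):
        for rep in range(1, n_reps + 1):
            noise = rng.normal(0.0, rep_noise_sd, size=n_metabolites)
            for k, met in enumerate(ids):
                lvl = base[k] + noise[k]
                if gi > 0:
                    lvl += effects.get(met, 0.0)
                rows.append((met, group, rep, 2.0 ** lvl))
    table = pd.DataFrame(rows, columns=["metabolite", "group", "replicate", "area"])
    truth = GroundTruth(
        true_group_effects={m: float(effects.get(m, 0.0)) for m in ids}
    )
    return table, truth
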