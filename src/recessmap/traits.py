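"""OGTT-derived phenotypes.

Glucose-tolerance classification (type 2 diabetes vs normal glucose
tolerance), HOMA-IR, Gutt's insulin sensitivity index ISI(0,120), the
Friedewald LDL formula, and within-stratum rank-based inverse-normal
(quantile) transformation of quantitative traits.

Units are enforced at the API boundary and never auto-detected:
glucose mmol/l, insulin pmol/l, weight kg.  The constant 6.945 converts
insulin from pmol/l to uU/ml.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "T2D",
    "NGT",
    "INDETERMINATE",
    "classify_glucose_tolerance",
    "homa_ir",
    "isi_0_120",
    "friedewald_ldl",
    "quantile_transform",
    "StratifiedQuantileTransformer",
    "derive_traits",
]

T2D = "T2D"
NGT = "NGT"
INDETERMINATE = "INDETERMINATE"

_INS_PMOL_PER_UU = 6.945

# Diagnostic thresholds (mmol/l).  Strict inequalities: equality with a
# case threshold is NOT a case, equality with a control threshold is NOT
# a control.
_FPG_CASE = 7.0
_GLU2H_CASE = 11.1
_FPG_CONTROL = 6.1
_GLU2H_CONTROL = 7.8


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_glucose_tolerance(fpg=None, glu2h=None, selfreport_dm=None) -> str:
    """Classify one individual as T2D, NGT or INDETERMINATE.

    T2D: self-reported diabetes, or fasting glucose > 7 mmol/l, or 2 h
    glucose > 11.1 mmol/l.  NGT: fasting < 6.1 AND 2 h < 7.8 AND no
    self-report.  Anything else (including records too incomplete to
    satisfy the control rule) is INDETERMINATE.  Self-report overrides
    measured normoglycaemia.
    """
    miss_f, miss_g = _is_missing(fpg), _is_missing(glu2h)
    miss_s = selfreport_dm is None
    if miss_f and miss_g and miss_s:
        raise ValueError(
            "cannot classify glucose tolerance: fasting glucose, 2 h glucose "
            "and self-report are all missing"
        )
    if (not miss_s and bool(selfreport_dm)) or (not miss_f and fpg > _FPG_CASE) or (
        not miss_g and glu2h > _GLU2H_CASE
    ):
        return T2D
    if (
        not miss_f
        and not miss_g
        and fpg < _FPG_CONTROL
        and glu2h < _GLU2H_CONTROL
        and not (not miss_s and bool(selfreport_dm))
    ):
        return NGT
    return INDETERMINATE


def homa_ir(fpg: float, fins: float) -> float:
    """HOMA insulin-resistance index: fpg * (fins / 6.945) / 22.5.

    fpg in mmol/l, fins in pmol/l (converted internally to uU/ml).
    """
    fpg = np.asarray(fpg, dtype=float)
    fins = np.asarray(fins, dtype=float)
    if np.any(fpg <= 0) or np.any(fins <= 0):
        raise ValueError("homa_ir requires positive glucose and insulin")
    out = fpg * (fins / _INS_PMOL_PER_UU) / 22.5
    return float(out) if out.ndim == 0 else out


def isi_0_120(fpg, glu2h, fins, ins2h, weight):
    """Gutt's insulin sensitivity index ISI(0,120).

    m = (75000 + (fpg - glu2h) * 18 * 0.19 * weight) / 120 is the glucose
    uptake rate (mg/min; 75000 mg is the oral load, 18 converts mmol/l to
    mg/dl, 0.19*weight approximates the glucose space in litres).  The
    index is m divided by mean plasma glucose (mmol/l) and by the natural
    log of mean serum insulin in uU/ml.

    Scalar inputs raise on a non-positive log argument; array inputs flag
    the offending records as NaN instead of failing the batch.
    """
    scalar = np.isscalar(fpg)
    fpg, glu2h, fins, ins2h, weight = (
        np.asarray(v, dtype=float) for v in (fpg, glu2h, fins, ins2h, weight)
    )
    for name, v in (("fpg", fpg), ("glu2h", glu2h), ("fins", fins),
                    ("ins2h", ins2h), ("weight", weight)):
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError(f"isi_0_120 requires positive {name}")
    m = (75000.0 + (fpg - glu2h) * 18.0 * 0.19 * weight) / 120.0
    mean_glu = (fpg + glu2h) / 2.0
    mean_ins_uu = ((fins + ins2h) / 2.0) / _INS_PMOL_PER_UU
    with np.errstate(invalid="ignore", divide="ignore"):
        log_ins = np.log(mean_ins_uu)
        out = np.where(mean_ins_uu > 1.0, m / mean_glu / log_ins, np.nan)
    if scalar:
        out = float(out)
        if math.isnan(out) and not any(
            math.isnan(float(v)) for v in (fpg, glu2h, fins, ins2h, weight)
        ):
            raise ValueError(
                "isi_0_120 undefined: mean insulin <= 1 uU/ml (log argument <= 1)"
            )
    return out


def friedewald_ldl(total_chol, hdl, triglycerides):
    """Friedewald LDL-cholesterol (all mmol/l): TC - HDL - TG/2.2."""
    return np.asarray(total_chol, float) - np.asarray(hdl, float) - np.asarray(
        triglycerides, float
    ) / 2.2


class StratifiedQuantileTransformer:
    """Rank-based inverse-normal transform within strata.

    Within each stratum (e.g. sex x cohort), non-missing values are ranked
    (average ranks for ties) and mapped to standard-normal quantiles via
    Phi^-1((r - 0.5) / n_stratum); missing values stay missing.  The
    transform is rank-only: it preserves within-stratum order and ignores
    the raw scale.

    The transformer is stateless (ranks are recomputed per call), so
    ``fit`` only validates and ``transform`` does the work, keeping the
    sklearn transformer contract.
    """

    def __init__(self, min_stratum_size: int = 2):
        self.min_stratum_size = min_stratum_size

    def get_params(self, deep=True):
        return {"min_stratum_size": self.min_stratum_size}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, values, strata=None):
        self._validate(values, strata)
        self.n_strata_ = len(self._groups(values, strata))
        return self

    def _validate(self, values, strata):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be 1-D")
        if strata is not None and len(np.asarray(strata, dtype=object)) != values.size:
            raise ValueError("strata must align with values")

    @staticmethod
    def _groups(values, strata):
        n = len(values)
        if strata is None:
            labels = [0] * n
        else:
            labels = [tuple(lab) if isinstance(lab, (np.ndarray, list)) else lab
                      for lab in strata]
        out = {}
        for i, lab in enumerate(labels):
            out.setdefault(lab, []).append(i)
        return out

    def transform(self, values, strata=None):
        self._validate(values, strata)
        x = np.asarray(values, dtype=float)
        z = np.full_like(x, np.nan)
        for lab, idx in self._groups(x, strata).items():
            idx = np.asarray(idx)
            obs = idx[np.isfinite(x[idx])]
            if obs.size < self.min_stratum_size:
                raise ValueError(
                    f"stratum {lab!r} has only {obs.size} non-missing value(s); "
                    f"need >= {self.min_stratum_size}"
                )
            ranks = stats.rankdata(x[obs], method="average")
            z[obs] = stats.norm.ppf((ranks - 0.5) / obs.size)
        return z

    def fit_transform(self, values, strata=None):
        return self.fit(values, strata).transform(values, strata)


def quantile_transform(values, strata=None) -> np.ndarray:
    """Within-stratum rank-based inverse-normal transform (see
    :class:`StratifiedQuantileTransformer`)."""
    return StratifiedQuantileTransformer().fit_transform(values, strata)


_TRAIT_FUNCS = ("homa_ir", "isi_0_120")


def derive_traits(
    pheno: pd.DataFrame,
    traits=("fpg_mmol_l", "glu2h_mmol_l", "fins_pmol_l", "ins2h_pmol_l",
            "homa_ir", "isi_0_120"),
    strata=("sex", "cohort"),
) -> pd.DataFrame:
    """Add derived phenotype columns to a cohort table.

    Adds ``gt_class`` (T2D/NGT/INDETERMINATE), ``homa_ir`` and
    ``isi_0_120`` where requested, plus one ``z_<trait>`` column per trait
    quantile-transformed within the given strata.
    """
    out = pheno.copy()
    selfrep = out.get("selfreport_dm")
    out["gt_class"] = [
        classify_glucose_tolerance(
            fpg=row_f, glu2h=row_g,
            selfreport_dm=None if selfrep is None else bool(selfrep.iloc[i]),
        )
        for i, (row_f, row_g) in enumerate(
            zip(out["fpg_mmol_l"], out["glu2h_mmol_l"])
        )
    ]
    if "homa_ir" in traits:
        fpg, fins = out["fpg_mmol_l"], out["fins_pmol_l"]
        ok = (fpg > 0) & (fins > 0)
        vals = np.full(len(out), np.nan)
        vals[ok.to_numpy()] = homa_ir(fpg[ok].to_numpy(), fins[ok].to_numpy())
        out["homa_ir"] = vals
    if "isi_0_120" in traits:
        out["isi_0_120"] = isi_0_120(
            out["fpg_mmol_l"].to_numpy(),
            out["glu2h_mmol_l"].to_numpy(),
            out["fins_pmol_l"].to_numpy(),
            out["ins2h_pmol_l"].to_numpy(),
            out["weight_kg"].to_numpy(),
        )
    labels = list(zip(*(out[s] for s in strata))) if strata else None
    for trait in traits:
        if trait not in out.columns:
            raise KeyError(f"trait column {trait!r} not found")
        out[f"z_{trait}"] = quantile_transform(out[trait].to_numpy(float), labels)
    return out
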