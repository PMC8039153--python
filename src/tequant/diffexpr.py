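"""Negative-binomial differential expression and downstream summaries.

A deliberately transparent re-implementation of the standard NB
workflow: median-of-ratios size factors, per-feature method-of-moments
dispersion pooled across conditions, a delta-method Wald test on the
log2 difference of normalized condition means, and BH-FDR.  No
empirical-Bayes dispersion sharing and no fold-change shrinkage: L2FC is
computed on normalized condition means with a +0.5 pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import CountTable, TERecord
from .stats import bh_adjust

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DiffResult:
    feature_id: str
    base_mean: float
    l2fc: float
    p_value: float
    padj: float
    direction: str  # up / down / ns


def estimate_size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over all-positive features of
    count / geometric-mean-across-samples.  Raises if no feature is
    positive in every sample.
    """
    counts = table.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature with all-positive counts; consider adding a "
            "pseudocount to every cell before normalization"
        )
    sub = counts[all_pos]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature MoM dispersion pooled across conditions, floor 1e-8."""
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        n = sub.shape[1]
        if n < 2:
            raise ValueError("need ≥2 replicates per condition for dispersion")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += alpha * (n - 1)
        den += n - 1
    return np.maximum(num / den, 1e-8)


def nb_wald_test(
    table: CountTable,
    l2fc_threshold: float = 0.0,
    condition_order: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB Wald test of the second condition vs the first.

    Returns a DataFrame indexed by feature id with columns base_mean,
    l2fc, p_value, padj and direction.  L2FC is log2((mean2 + 0.5) /
    (mean1 + 0.5)) on size-factor-normalized condition means; the Wald
    standard error comes from the NB variance of each condition mean via
    the delta method.  Features with zero counts everywhere get p = 1
    and l2fc = 0.  BH adjustment runs over all tested features;
    direction is up/down only when padj < ``alpha`` and |l2fc| exceeds
    ``l2fc_threshold``.
    """
    conds = condition_order or tuple(table.conditions)
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    ref, alt = conds
    idx_ref = [table.sample_ids.index(s) for s in table.samples_of(ref)]
    idx_alt = [table.sample_ids.index(s) for s in table.samples_of(alt)]
    if len(idx_ref) < 2 or len(idx_alt) < 2:
        raise ValueError("need ≥2 replicates per condition")

    counts = table.counts.to_numpy(dtype=float)
    sf = estimate_size_factors(table).to_numpy()
    norm = counts / sf

    m_ref = norm[:, idx_ref].mean(axis=1)
    m_alt = norm[:, idx_alt].mean(axis=1)
    base_mean = norm.mean(axis=1)
    disp = _pooled_dispersion(norm, [np.array(idx_ref), np.array(idx_alt)])

    mr = m_ref + 0.5
    ma = m_alt + 0.5
    l2fc = np.log2(ma / mr)
    # Var(log2 mean_c) ≈ (m + α m²) / (n · m² · ln2²) by the delta method
    var_ref = (mr + disp * mr**2) / (len(idx_ref) * mr**2 * LN2**2)
    var_alt = (ma + disp * ma**2) / (len(idx_alt) * ma**2 * LN2**2)
    se = np.sqrt(var_ref + var_alt)
    z = l2fc / se
    # the SE rests on a variance estimated with n1+n2-2 residual df, so a
    # Student-t reference keeps the test calibrated at small n
    df_resid = len(idx_ref) + len(idx_alt) - 2
    p = 2.0 * sps.t.sf(np.abs(z), df_resid)

    all_zero = counts.sum(axis=1) == 0
    p[all_zero] = 1.0
    l2fc[all_zero] = 0.0

    padj = bh_adjust(p)
    direction = np.where(
        (padj < alpha) & (l2fc > l2fc_threshold),
        "up",
        np.where((padj < alpha) & (l2fc < -l2fc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "l2fc": l2fc,
            "p_value": p,
            "padj": padj,
            "direction": direction,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def classify_te_direction(
    results: pd.DataFrame, class_of: dict[str, str]
) -> pd.DataFrame:
    """Class × direction contingency table of significant TE families.

    ``class_of`` maps feature id (family name) to TE class.  Rows are
    the four named classes in fixed order; 'other' and non-significant
    features are excluded.
    """
    rows = ["DNA", "LTR", "LINE", "SINE"]
    out = pd.DataFrame(0, index=rows, columns=["up", "down"])
    sig = results[results["direction"] != "ns"]
    for fid, row in sig.iterrows():
        cls = class_of.get(fid)
        if cls in rows:
            out.loc[cls, row["direction"]] += 1
    out.index.name = "te_class"
    return out


def class_composition_test(table: pd.DataFrame):
    """Pearson chi-square of independence on a class × direction table.

    Rows whose expected counts would be zero (empty rows/columns) are
    dropped with a warning.  Returns (statistic, df, p).  No Yates
    correction.
    """
    import logging

    tab = table.to_numpy(dtype=float)
    keep_rows = tab.sum(axis=1) > 0
    keep_cols = tab.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logging.getLogger(__name__).warning(
            "dropping empty rows/columns from contingency table"
        )
        tab = tab[keep_rows][:, keep_cols]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need ≥2 non-empty rows and columns")
    stat, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), int(dof), float(p)


def cross_model_concordance(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    class_of: dict[str, str] | None = None,
    alpha: float = 0.05,
):
    """Quadrant counts and L2FC correlation over jointly significant features.

    Over features with padj < alpha in both result sets: counts in the
    four sign quadrants of (l2fc_a, l2fc_b), the concordant/discordant
    split, and Pearson r of the L2FC pairs overall and per TE class.
    """
    import logging

    shared = res_a.index.intersection(res_b.index)
    a = res_a.loc[shared]
    b = res_b.loc[shared]
    sig = (a["padj"] < alpha) & (b["padj"] < alpha)
    fa = a.loc[sig, "l2fc"].to_numpy()
    fb = b.loc[sig, "l2fc"].to_numpy()
    quadrants = {
        "up_up": int(((fa > 0) & (fb > 0)).sum()),
        "down_down": int(((fa < 0) & (fb < 0)).sum()),
        "up_down": int(((fa > 0) & (fb < 0)).sum()),
        "down_up": int(((fa < 0) & (fb > 0)).sum()),
    }
    concordant = quadrants["up_up"] + quadrants["down_down"]
    discordant = quadrants["up_down"] + quadrants["down_up"]
    if len(fa) >= 2 and np.std(fa) > 0 and np.std(fb) > 0:
        r_all = float(sps.pearsonr(fa, fb).statistic)
    else:
        logging.getLogger(__name__).warning(
            "too few jointly significant features for a correlation"
        )
        r_all = float("nan")
    per_class: dict[str, float] = {}
    if class_of is not None:
        ids = np.asarray(shared[sig.to_numpy()])
        classes = np.array([class_of.get(f, "other") for f in ids])
        for cls in sorted(set(classes)):
            m = classes == cls
            if m.sum() >= 2 and np.std(fa[m]) > 0 and np.std(fb[m]) > 0:
                per_class[cls] = float(sps.pearsonr(fa[m], fb[m]).statistic)
            else:
                per_class[cls] = float("nan")
    return {
        "quadrants": quadrants,
        "concordant": concordant,
        "discordant": discordant,
        "pearson_r": r_all,
        "pearson_r_by_class": per_class,
        "n_shared_significant": int(sig.sum()),
    }


def compute_ddct(
    ct_target: pd.Series, ct_reference: pd.Series, control_group: list[str]
) -> pd.DataFrame:
    """Relative qPCR quantification (ΔΔCt).

    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the mean
    control ΔCt; fold change = 2^(−ΔΔCt); L2FC = −ΔΔCt.
    """
    if not control_group:
        raise ValueError("control group must be non-empty")
    missing = [s for s in ct_target.index if s not in ct_reference.index
               or pd.isna(ct_reference.get(s))]
    if missing:
        raise ValueError(f"missing reference Ct for samples: {missing}")
    dct = ct_target - ct_reference.loc[ct_target.index]
    control_mean = dct.loc[control_group].mean()
    ddct = dct - control_mean
    return pd.DataFrame(
        {
            "delta_ct": dct,
            "ddct": ddct,
            "fold_change": 2.0 ** (-ddct),
            "l2fc": -ddct,
        }
    )
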