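"""Two-group differential expression and gene-set enrichment.

Implements the empirical-Bayes moderated t-test (per-gene residual
variances shrunk toward an inverse-chi-square prior whose hyperparameters
``(d0, s0^2)`` are estimated by digamma/trigamma method-of-moments on the
log variances), Benjamini-Hochberg adjustment, flat hypergeometric
gene-set enrichment/depletion, a weighted Kolmogorov-Smirnov (GSEA-style)
enrichment score with phenotype permutation, and marker/DEG overlap
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

#: genes are called differentially expressed below this adjusted p
DEG_ALPHA = 0.05
#: default hypergeometric reporting threshold
ENRICHMENT_P_MAX = 0.001

_D0_CAP = 1e12  # finite stand-in for d0 = +inf in degrees of freedom


@dataclass
class ModerationParams:
    """Prior degrees of freedom and prior variance of the moderated test."""

    d0: float  # may be inf (complete shrinkage)
    s0_sq: float


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the variance prior from per-gene variances.

    Moment equations on ``log(s2)``: the mean identifies ``s0^2`` and the
    excess spread over ``trigamma(df/2)`` identifies ``d0``.  A non-positive
    trigamma moment means the variances are under-dispersed relative to
    chi-square sampling noise, and ``d0 = +inf`` (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; cannot moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if len(e) < 2:
        return ModerationParams(d0=0.0, s0_sq=float(np.exp(e_mean)))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(m: pd.DataFrame, groups: pd.Series,
                     target: str | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    Parameters
    ----------
    m
        genes x samples matrix (log2 scale), informative genes only.
    groups
        Two-level label per sample; ``target`` names the group whose mean
        enters the fold change positively (default: the lexically first
        level, i.e. log_fc = mean(target) - mean(control), "up" =
        higher in the target group).

    Returns
    -------
    DataFrame indexed by gene with columns ``log_fc``, ``s2_g``, ``df_g``,
    ``t_mod``, ``p_value``, ``p_adj``; the fitted prior is stored in
    ``.attrs["moderation"]``.
    """
    groups = pd.Series(groups).loc[m.columns]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(levels)}")
    if target is None:
        target = sorted(levels)[0]
    control = [lv for lv in levels if lv != target][0]
    idx1 = (groups == target).to_numpy()
    idx2 = (groups == control).to_numpy()
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 samples (got {n1}, {n2})")

    x = m.to_numpy(dtype=float)
    m1, m2 = x[:, idx1].mean(axis=1), x[:, idx2].mean(axis=1)
    log_fc = m1 - m2
    df = n1 + n2 - 2
    ss = ((x[:, idx1] - m1[:, None]) ** 2).sum(axis=1) + \
         ((x[:, idx2] - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if m.shape[0] < 2:
        warnings.warn("single gene: falling back to the ordinary t-test",
                      stacklevel=2)
        params = ModerationParams(d0=0.0, s0_sq=float(s2[0]) if s2[0] > 0 else 1.0)
        s2_tilde = s2
        df_total = np.full_like(s2, float(df))
    else:
        params = estimate_moderation(s2, df)
        if np.isinf(params.d0):
            s2_tilde = np.full_like(s2, params.s0_sq)
            df_total = np.full_like(s2, _D0_CAP)
        else:
            s2_tilde = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
            df_total = np.full_like(s2, params.d0 + df)

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "s2_g": s2,
            "df_g": float(df),
            "t_mod": t_mod,
            "p_value": p,
            "p_adj": bh_adjust(p),
        },
        index=m.index.copy(),
    )
    table.attrs["moderation"] = params
    table.attrs["target"] = target
    table.attrs["control"] = control
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(hits, collection: dict[str, list[str]], background,
                         p_max: float = ENRICHMENT_P_MAX) -> pd.DataFrame:
    """Flat hypergeometric enrichment/depletion of hit genes in gene sets.

    ``hits`` must be a subset of ``background``.  For each set,
    K = |set ∩ background| and k = |set ∩ hits|; the enrichment p-value is
    P(X >= k) and the depletion p-value P(X <= k) for
    X ~ Hypergeom(N, K, n).  Sets with min(p) < ``p_max`` are returned,
    sorted by that p ascending.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    hits = set(hits)
    stray = hits - background
    if stray:
        raise ValueError(f"hits not contained in background: {sorted(stray)[:5]}")
    n_bg, n_hits = len(background), len(hits)
    rows = []
    for name, members in collection.items():
        in_bg = set(members) & background
        k_set = len(in_bg)
        k_hit = len(in_bg & hits)
        p_enrich = float(stats.hypergeom.sf(k_hit - 1, n_bg, k_set, n_hits))
        p_deplete = float(stats.hypergeom.cdf(k_hit, n_bg, k_set, n_hits))
        p_min = min(p_enrich, p_deplete)
        rows.append({
            "set_name": name, "k": k_hit, "K": k_set, "n": n_hits, "N": n_bg,
            "p_enrich": p_enrich, "p_deplete": p_deplete,
            "p_hyper": p_min,
            "direction": "enriched" if p_enrich <= p_deplete else "depleted",
        })
    table = pd.DataFrame(rows,
                         columns=["set_name", "k", "K", "n", "N", "p_enrich",
                                  "p_deplete", "p_hyper", "direction"])
    table = table[table["p_hyper"] < p_max]
    return table.sort_values("p_hyper", kind="stable").reset_index(drop=True)


def _signal_to_noise(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    m1, m2 = x[:, idx1].mean(axis=1), x[:, idx2].mean(axis=1)
    s1, s2 = x[:, idx1].std(axis=1, ddof=1), x[:, idx2].std(axis=1, ddof=1)
    denom = np.maximum(s1 + s2, 1e-12)
    return (m1 - m2) / denom


def _enrichment_score(ranked_stats: np.ndarray, is_member: np.ndarray,
                      weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(ranked_stats)
    n_hit = int(is_member.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the matrix")
    if n_hit == n:
        return 0.0  # no complement to decrement against
    w = np.abs(ranked_stats) ** weight
    hit_mass = np.where(is_member, w, 0.0)
    total = hit_mass.sum()
    if total == 0:
        hit_mass = is_member.astype(float)
        total = float(n_hit)
    running = np.cumsum(hit_mass / total - (~is_member) / (n - n_hit))
    return float(running[np.argmax(np.abs(running))])


def gsea_enrichment(m: pd.DataFrame, phenotype: pd.Series, gene_set,
                    n_perm: int = 1000, seed: int = 0, target: str | None = None,
                    weight: float = 1.0):
    """GSEA-style enrichment of one gene set against a two-group phenotype.

    Genes are ranked by the signal-to-noise statistic; the enrichment score
    is the signed maximum deviation of the weighted (exponent 1) KS running
    sum; the null comes from seeded phenotype permutations.  Returns
    ``(ES, NES, p)`` with NES = ES / mean(|null ES| of the same sign) and p
    the add-one fraction of same-sign null scores at least as extreme.
    """
    phenotype = pd.Series(phenotype).loc[m.columns]
    levels = pd.unique(phenotype)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 phenotype groups, found {list(levels)}")
    if target is None:
        target = sorted(levels)[0]
    idx1 = (phenotype == target).to_numpy()
    idx2 = ~idx1
    if idx1.sum() < 3 or idx2.sum() < 3:
        raise ValueError("both phenotype groups need >= 3 samples")
    members = m.index.isin(set(gene_set))
    if not members.any():
        raise ValueError("gene set does not intersect the matrix genes")

    x = m.to_numpy(dtype=float)
    stats_obs = _signal_to_noise(x, idx1, idx2)
    if np.allclose(stats_obs, stats_obs[0]):
        raise ValueError("degenerate ranking: all gene statistics are equal")

    def score(s2n: np.ndarray) -> float:
        order = np.argsort(-s2n, kind="stable")
        return _enrichment_score(s2n[order], members[order], weight)

    es = score(stats_obs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    labels = idx1.copy()
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null[i] = score(_signal_to_noise(x, perm, ~perm))

    same_sign = null >= 0 if es >= 0 else null < 0
    null_same = null[same_sign]
    if len(null_same) == 0:
        return float(es), float("nan"), 0.0
    mean_abs = np.abs(null_same).mean()
    nes = es / mean_abs if mean_abs > 0 else np.nan
    p = float((np.abs(null_same) >= abs(es)).mean())
    return float(es), float(nes), p


def _percent(k: int, n: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty base."""
    if n == 0:
        return 0.0
    return float(Decimal(100.0 * k / n).quantize(Decimal("0.1"),
                                                 rounding=ROUND_HALF_UP))


def overlap_summary(markers: pd.DataFrame, degs: pd.DataFrame,
                    aux_lists: dict[str, list[str]] | None = None,
                    alpha: float = DEG_ALPHA) -> dict:
    """Counts/percentages of marker-DEG overlap and auxiliary-list coverage.

    Reports how many marker genes are significant DEGs, and what share of
    each auxiliary list (e.g. M1-/M2-associated genes) falls among the
    markers and among the significant DEGs.
    """
    marker_genes = set(markers.index)
    sig = set(degs.index[degs["p_adj"] < alpha])
    inter = marker_genes & sig
    report = {
        "n_markers": len(marker_genes),
        "n_degs": len(sig),
        "n_degs_up": int(((degs["p_adj"] < alpha) & (degs["log_fc"] > 0)).sum()),
        "n_degs_down": int(((degs["p_adj"] < alpha) & (degs["log_fc"] < 0)).sum()),
        "markers_in_degs": {
            "count": len(inter),
            "percent_of_markers": _percent(len(inter), len(marker_genes)),
        },
        "aux": {},
    }
    for name, genes in (aux_lists or {}).items():
        gset = set(genes)
        report["aux"][name] = {
            "size": len(gset),
            "in_markers": {
                "count": len(gset & marker_genes),
                "percent": _percent(len(gset & marker_genes), len(gset)),
            },
            "in_degs": {
                "count": len(gset & sig),
                "percent": _percent(len(gset & sig), len(gset)),
            },
        }
    return report
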