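"""Moderated differential expression across phase groups with Storey q-values.

The workflow follows the standard multi-group microarray analysis: one joint
linear model (group means) over all phases, a pooled per-gene residual
variance, an empirical-Bayes scaled-inverse-chi-square prior fitted to the
variances by moment matching on the log scale, and per-contrast moderated
t-statistics

    t_g = (mean_a - mean_b) / (s_tilde_g * sqrt(1/n_a + 1/n_b)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

referred to a t distribution with ``d0 + d_g`` degrees of freedom.  Multiple
testing is handled by Storey's q-value with the smoother pi0 estimate.
Setting the prior degrees of freedom ``d0 = 0`` recovers the ordinary pooled
two-sample t-test, which the tests use as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModeratedVariancePrior",
    "GroupFit",
    "fit_group_model",
    "estimate_prior",
    "moderated_test",
    "storey_pi0",
    "storey_qvalues",
    "classify_calls",
    "run_pairwise",
    "subtype_check",
    "DEResults",
    "PHASE_CONTRASTS",
]

#: the three pairwise phase contrasts, orientation log2FC = mean(a) - mean(b)
PHASE_CONTRASTS = (
    ("accelerated", "chronic"),
    ("blast", "accelerated"),
    ("blast", "chronic"),
)


@dataclass
class ModeratedVariancePrior:
    """Scaled inverse-chi-square prior on per-gene residual variances."""

    d0: float  # prior degrees of freedom, may be +inf (full shrinkage)
    s0_sq: float

    def posterior_var(self, s_sq: np.ndarray, d_g: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + d_g * s_sq) / (self.d0 + d_g)


@dataclass
class GroupFit:
    """Per-gene group means and pooled residual variance of the joint model."""

    means: pd.DataFrame  # genes x groups
    s_sq: pd.Series  # pooled residual variance per gene
    df_resid: float  # n_total - n_groups
    group_sizes: dict[str, int]


def fit_group_model(
    matrix: pd.DataFrame, meta: pd.DataFrame, groups: list[str]
) -> GroupFit:
    """Fit the one-way group-means model jointly over the named groups."""
    sizes: dict[str, int] = {}
    means = {}
    rss = np.zeros(matrix.shape[0])
    n_total = 0
    for g in groups:
        ids = meta.loc[meta["phase"] == g, "sample_id"]
        cols = [c for c in matrix.columns if c in set(ids)]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sizes[g] = len(cols)
        sub = matrix[cols].to_numpy()
        mu = sub.mean(axis=1)
        means[g] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        n_total += len(cols)
    df = n_total - len(groups)
    s_sq = pd.Series(rss / df, index=matrix.index)
    return GroupFit(
        means=pd.DataFrame(means, index=matrix.index),
        s_sq=s_sq,
        df_resid=float(df),
        group_sizes=sizes,
    )


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s_sq: np.ndarray, d_g: float) -> ModeratedVariancePrior:
    """Moment-match the variance prior on e_g = log(s_g^2).

    If s^2 ~ s0^2 * F(d_g, d0) then E[e] and Var[e] are digamma/trigamma
    expressions in (d_g, d0); matching the empirical mean and variance of e
    yields the prior.  When the empirical variance does not exceed the pure
    sampling variance trigamma(d_g/2), the prior is degenerate (d0 = +inf).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if s_sq.size < 10:
        raise ValueError("need at least 10 genes with positive residual variance")
    if np.ptp(s_sq) == 0:
        return ModeratedVariancePrior(d0=np.inf, s0_sq=float(s_sq[0]))
    # E[log(chi2_k / k)] = digamma(k/2) - log(k/2); with s^2 ~ s0^2 F(d_g, d0),
    # E[e] = log(s0^2) + bias(d_g) - bias(d0) and Var[e] = trigamma(d_g/2)
    # + trigamma(d0/2).
    e = np.log(s_sq)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    samp_var = float(special.polygamma(1, d_g / 2.0))
    bias_g = float(special.digamma(d_g / 2.0) - np.log(d_g / 2.0))
    excess = e_var - samp_var
    if excess <= 0:
        return ModeratedVariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean - bias_g)))
    d0 = 2.0 * _trigamma_inverse(excess)
    bias_0 = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    s0_sq = float(np.exp(e_mean - bias_g + bias_0))
    return ModeratedVariancePrior(d0=float(d0), s0_sq=s0_sq)


def moderated_test(
    fit: GroupFit,
    prior: ModeratedVariancePrior,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Moderated t-test for the contrast mean(a) - mean(b).

    With ``prior.d0 == 0`` this is the ordinary pooled two-sample t-test.
    Zero posterior variance is resolved by convention: p = 0 when the fold
    change is nonzero, p = 1 otherwise.
    """
    lfc = (fit.means[group_a] - fit.means[group_b]).to_numpy()
    n_a, n_b = fit.group_sizes[group_a], fit.group_sizes[group_b]
    if prior.d0 == 0:
        var_post = fit.s_sq.to_numpy()
        df_total = fit.df_resid
    else:
        var_post = prior.posterior_var(fit.s_sq.to_numpy(), fit.df_resid)
        df_total = prior.d0 + fit.df_resid
    se = np.sqrt(var_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
        t = np.where((se == 0) & (lfc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)
    return pd.DataFrame(
        {"log2fc": lfc, "t_mod": t, "p": p}, index=fit.means.index
    )


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
    0.05, 0.10, ..., 0.95; a cubic fit of pi0(lambda) is evaluated at the
    largest lambda and clipped to (0, 1].  For short p-vectors (m < 100) the
    smoother is unstable and the conservative max over the grid is used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if p.size < 100:
        return float(min(1.0, max(pi0_l.max(), 1.0 / p.size)))
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(min(1.0, max(pi0, 1.0 / p.size)))


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with ``pi0=1`` this is exactly Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_calls(
    log2fc: np.ndarray,
    q: np.ndarray,
    q_cut: float = 0.05,
    lfc_cut: float | None = None,
) -> np.ndarray:
    """Expression-change call per gene: 'under', 'over' or 'unchanged'."""
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    thresh = 0.0 if lfc_cut is None else float(lfc_cut)
    sig = q <= q_cut
    calls = np.full(log2fc.shape, "unchanged", dtype=object)
    if lfc_cut is None:
        calls[sig & (log2fc < 0)] = "under"
        calls[sig & (log2fc > 0)] = "over"
    else:
        calls[sig & (log2fc <= -thresh)] = "under"
        calls[sig & (log2fc >= thresh)] = "over"
    return calls


class DEResults:
    """Results of the pairwise-phase differential expression analysis.

    Attributes
    ----------
    tables : dict[str, pandas.DataFrame]
        One table per contrast (key ``"a_vs_b"``) with columns
        ``log2fc, t_mod, p, q, call``.
    signature : list[str]
        Union of genes called (q <= q_cut) in any contrast.
    prior : ModeratedVariancePrior
    """

    def __init__(self, tables, signature, prior, fit, q_cut, lfc_cut):
        self.tables = tables
        self.signature = signature
        self.prior = prior
        self.fit = fit
        self.q_cut = q_cut
        self.lfc_cut = lfc_cut

    def n_called(self, contrast: str) -> int:
        return int((self.tables[contrast]["call"] != "unchanged").sum())

    def summary(self) -> str:
        lines = [
            "Pairwise-phase differential expression",
            f"  genes: {len(next(iter(self.tables.values())))}"
            f"   prior d0: {self.prior.d0:.3g}   s0^2: {self.prior.s0_sq:.3g}",
            f"  cutoffs: q <= {self.q_cut}"
            + (f", |log2fc| >= {self.lfc_cut}" if self.lfc_cut else ""),
        ]
        for name, tab in self.tables.items():
            n_under = int((tab["call"] == "under").sum())
            n_over = int((tab["call"] == "over").sum())
            lines.append(
                f"  {name}: {n_under + n_over} called"
                f" ({n_under} under, {n_over} over)"
            )
        lines.append(f"  signature size (union): {len(self.signature)}")
        return "\n".join(lines)

    def write_tables(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        paths = {}
        for name, tab in self.tables.items():
            path = Path(out_dir) / f"de_{name}.tsv"
            out = tab.copy()
            out.index.name = "gene_id"
            out.to_csv(path, sep="\t", float_format="%.6g")
            paths[name] = str(path)
        return paths


def run_pairwise(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    q_cut: float = 0.05,
    lfc_cut: float | None = None,
    include_resistant: bool = False,
    pi0: float | None = None,
) -> DEResults:
    """Run the three pairwise phase contrasts (plus resistant contrasts).

    One joint group-means model is fitted over all included groups so that
    every contrast shares the pooled variance estimate; q-values are computed
    per contrast; the signature is the union of called genes over the three
    phase contrasts.
    """
    groups = ["chronic", "accelerated", "blast"]
    contrasts = list(PHASE_CONTRASTS)
    if include_resistant:
        groups.append("resistant")
        contrasts += [("resistant", g) for g in ("chronic", "accelerated", "blast")]
    fit = fit_group_model(matrix, meta, groups)
    prior = estimate_prior(fit.s_sq.to_numpy(), fit.df_resid)
    tables = {}
    for a, b in contrasts:
        tab = moderated_test(fit, prior, a, b)
        tab["q"] = storey_qvalues(tab["p"].to_numpy(), pi0=pi0)
        tab["call"] = classify_calls(
            tab["log2fc"].to_numpy(), tab["q"].to_numpy(), q_cut, lfc_cut
        )
        tables[f"{a}_vs_{b}"] = tab
    signature_mask = np.zeros(matrix.shape[0], dtype=bool)
    for a, b in PHASE_CONTRASTS:
        signature_mask |= (tables[f"{a}_vs_{b}"]["call"] != "unchanged").to_numpy()
    signature = list(matrix.index[signature_mask])
    return DEResults(tables, signature, prior, fit, q_cut, lfc_cut)


def subtype_check(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    q_cut: float = 0.05,
    merge_threshold: int = 10,
) -> dict:
    """Compare the two accelerated-phase subtypes (blast-count vs cytogenetic).

    Returns the moderated DE table, the number of genes called at ``q_cut``
    and a merge recommendation (True when the count falls below
    ``merge_threshold``, i.e. the subtypes can be treated as one group).
    """
    accel = meta[meta["phase"] == "accelerated"].copy()
    sub_meta = accel.rename(columns={"accelerated_subtype": "subtype"})
    sub_meta = sub_meta.assign(phase=sub_meta["subtype"])
    for sub in ("blast_count", "cytogenetic"):
        if (sub_meta["phase"] == sub).sum() < 2:
            raise ValueError(f"accelerated subtype {sub!r} has fewer than 2 samples")
    cols = [c for c in matrix.columns if c in set(sub_meta["sample_id"])]
    fit = fit_group_model(matrix[cols], sub_meta, ["blast_count", "cytogenetic"])
    prior = estimate_prior(fit.s_sq.to_numpy(), fit.df_resid)
    tab = moderated_test(fit, prior, "blast_count", "cytogenetic")
    tab["q"] = storey_qvalues(tab["p"].to_numpy())
    tab["call"] = classify_calls(tab["log2fc"].to_numpy(), tab["q"].to_numpy(), q_cut)
    n_called = int((tab["call"] != "unchanged").sum())
    return {
        "table": tab,
        "n_called": n_called,
        "merge_recommended": n_called < merge_threshold,
    }
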