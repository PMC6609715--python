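"""Library-level statistics for pooled tag libraries.

Includes the FACS-bin fluorescence-intensity estimator: with bins
b = 1..n, known sorted fractions p_b and UMI counts r_{g,b} for genotype g,
the unnormalized cell distribution is

    C~_g(b) = r_{g,b} / sum_{g in G} r_{g,b} * p_b

and the fluorescence intensity estimate is the empirical mean of the bin
index under C~_g,

    estimate(g) = sum_b b * C~_g(b) / sum_b C~_g(b).

The module also provides median normalization of UMI counts, RCA/PCR fold
changes, coverage/overlap set statistics, replicate correlations, pre/post
enrichment, Fisher-exact feature association, and the co-integrand
estimator (phenotypic heterozygotes are half of all double integrants at
equimolar uptake).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# FACS-bin intensity estimation
# ---------------------------------------------------------------------------


@dataclass
class BinProfile:
    """Ordered FACS bins with their sorted population fractions."""

    fractions: tuple[float, ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.fractions):
            raise ValueError("bin fractions must be positive")
        if self.names is None:
            self.names = tuple(f"bin{i + 1}" for i in range(len(self.fractions)))

    @property
    def p_b(self) -> pd.Series:
        p = np.asarray(self.fractions, dtype=float)
        return pd.Series(p / p.sum(), index=list(self.names))


def bin_distribution(counts: pd.DataFrame, profile: BinProfile) -> pd.DataFrame:
    """Unnormalized per-genotype cell distribution C~_g(b).

    ``counts`` is the genotype × bin read/UMI matrix r_{g,b} with columns in
    bin order.  Bins with zero total reads are dropped with a warning.
    """
    p = profile.p_b
    counts = counts.reindex(columns=p.index)
    totals = counts.sum(axis=0)
    dead = totals[totals == 0].index
    if len(dead):
        warnings.warn(f"dropping bins with zero total reads: {list(dead)}")
        counts = counts.drop(columns=dead)
        p = p.drop(index=dead)
        totals = totals.drop(index=dead)
    return counts.div(totals, axis=1).mul(p, axis=1)


def intensity_estimate(c_tilde: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Empirical mean bin index under C~_g; genotypes with an all-zero
    distribution are returned as NaN (flagged undefined)."""
    if isinstance(c_tilde, pd.Series):
        return float(intensity_estimate(c_tilde.to_frame().T).iloc[0])
    b = np.arange(1, c_tilde.shape[1] + 1, dtype=float)
    num = (c_tilde * b).sum(axis=1)
    den = c_tilde.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = num / den
    return est.where(den > 0)


def profile_library(counts: pd.DataFrame, profile: BinProfile) -> pd.DataFrame:
    """Convenience: C~ table plus the intensity estimate per genotype."""
    c = bin_distribution(counts, profile)
    out = c.copy()
    out["intensity_estimate"] = intensity_estimate(c)
    return out


# ---------------------------------------------------------------------------
# normalization and fold changes
# ---------------------------------------------------------------------------


def normalize_counts(counts: pd.Series | pd.DataFrame):
    """Divide each sample's counts by its median over detected designs."""
    if isinstance(counts, pd.Series):
        med = counts[counts > 0].median()
        if not med or np.isnan(med):
            raise ValueError("sample median is zero; cannot normalize")
        return counts / med
    return counts.apply(normalize_counts, axis=0)


def rca_fold_changes(
    rca_counts: pd.Series, pcr_counts: pd.Series, threshold: float = 2.0
) -> tuple[pd.Series, dict]:
    """Per-design fold change of normalized copy number, RCA over PCR.

    Designs absent from one sample are reported as lost/gained rather than
    given a fold change.  The summary reports the fraction of shared designs
    changing more than ``threshold``-fold in either direction.
    """
    rca_n = normalize_counts(rca_counts)
    pcr_n = normalize_counts(pcr_counts)
    shared = rca_n.index.intersection(pcr_n.index)
    shared = [i for i in shared if pcr_n[i] > 0 and rca_n[i] > 0]
    fc = (rca_n[shared] / pcr_n[shared]).astype(float)
    lost = sorted(set(pcr_counts.index[pcr_counts > 0]) - set(shared))
    gained = sorted(set(rca_counts.index[rca_counts > 0]) - set(shared))
    beyond = ((fc > threshold) | (fc < 1.0 / threshold)).mean() if len(fc) else float("nan")
    summary = {
        "n_shared": len(fc),
        "fraction_beyond_threshold": float(beyond),
        "lost": lost,
        "gained": gained,
    }
    return fc, summary


def coverage_overlap(
    libraries: dict[str, pd.Series | set], design_to_orf: dict[str, str]
) -> dict:
    """Design/ORF coverage of libraries and their pairwise/3-way overlaps."""
    detected = {
        name: set(s.index[s > 0]) if isinstance(s, pd.Series) else set(s)
        for name, s in libraries.items()
    }
    orfs = {
        name: {design_to_orf[d] for d in dets if d in design_to_orf}
        for name, dets in detected.items()
    }
    names = list(detected)
    out = {
        "designs_detected": {n: len(detected[n]) for n in names},
        "orfs_covered": {n: len(orfs[n]) for n in names},
        "orfs_union": len(set().union(*orfs.values())) if orfs else 0,
        "pairwise_orf_overlap": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out["pairwise_orf_overlap"][(a, b)] = len(orfs[a] & orfs[b])
    if len(names) >= 3:
        out["threeway_orf_overlap"] = len(set.intersection(*(orfs[n] for n in names[:3])))
    return out


def replicate_correlation(
    counts_a: pd.Series,
    counts_b: pd.Series,
    method: str = "pearson",
    log: bool = False,
) -> float:
    """Correlation of copy numbers between replicates on shared designs."""
    shared = counts_a.index.intersection(counts_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared designs")
    a, b = counts_a[shared].astype(float), counts_b[shared].astype(float)
    if log:
        a, b = np.log1p(a), np.log1p(b)
    if method == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def enrichment(
    pre_counts: pd.Series, post_counts: pd.Series, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Fold enrichment of each genotype between two sequenced pools.

    FE = (post frequency + eps) / (pre frequency + eps) with a pseudocount
    of ``pseudocount`` reads; genotypes present pre but absent post are
    classified depleted, the converse enriched-de-novo.
    """
    universe = pre_counts.index.union(post_counts.index)
    pre = pre_counts.reindex(universe, fill_value=0).astype(float)
    post = post_counts.reindex(universe, fill_value=0).astype(float)
    pre_f = (pre + pseudocount) / (pre.sum() + pseudocount)
    post_f = (post + pseudocount) / (post.sum() + pseudocount)
    fe = post_f / pre_f
    call = pd.Series("unchanged", index=universe, dtype=object)
    call[(pre > 0) & (post == 0)] = "depleted"
    call[(pre == 0) & (post > 0)] = "enriched_de_novo"
    call[(fe > 1) & (pre > 0) & (post > 0)] = call[
        (fe > 1) & (pre > 0) & (post > 0)
    ].replace("unchanged", "enriched")
    return pd.DataFrame({"pre": pre, "post": post, "fold_enrichment": fe, "call": call})


# ---------------------------------------------------------------------------
# feature association
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and Haldane-corrected odds ratio.

    ``table`` is [[a, b], [c, d]] — successes/failures by feature present/
    absent.  The p-value sums hypergeometric probabilities of all tables at
    least as extreme as the observed one (scipy's two-sided convention);
    0.5 is added to every cell for the odds ratio when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("degenerate margins")
    p = float(sps.fisher_exact(t.astype(int), alternative="two-sided").pvalue)
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return p, float((a * d) / (b * c))


def feature_association(
    outcomes: pd.DataFrame,
    success_col: str = "success",
    feature_cols: list[str] | None = None,
    fdr: bool = True,
) -> pd.DataFrame:
    """Per-feature 2×2 Fisher-exact association with tagging success.

    ``outcomes`` holds one row per clone/design with a boolean success label
    and boolean feature columns.  Raw p-values are reported; Benjamini-
    Hochberg adjusted values are added alongside when ``fdr``.
    """
    if feature_cols is None:
        feature_cols = [c for c in outcomes.columns if c != success_col]
    y = outcomes[success_col].astype(bool)
    rows = []
    for feat in feature_cols:
        x = outcomes[feat].astype(bool)
        tab = [
            [int((x & y).sum()), int((x & ~y).sum())],
            [int((~x & y).sum()), int((~x & ~y).sum())],
        ]
        try:
            p, orat = fisher_exact_2x2(tab)
        except ValueError:
            p, orat = float("nan"), float("nan")
        rows.append({"feature": feat, "p_value": p, "odds_ratio": orat, "table": tab})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        mask = out.p_value.notna()
        p = out.loc[mask, "p_value"].to_numpy()
        order = np.argsort(p)
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(p) + 1)
        q = np.minimum.accumulate((p * len(p) / ranks)[order][::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.minimum(q, 1.0)
        out.loc[mask, "p_bh"] = adj
    return out


# ---------------------------------------------------------------------------
# co-integrand model
# ---------------------------------------------------------------------------


def cointegration_model(
    uptake_ratio: float, n_draws: int = 100_000, seed: int = 0
) -> dict:
    """Heterozygous fraction among double integrants.

    Each double transformant takes up two cassettes independently, drawing
    cassette A with probability q = ``uptake_ratio``.  The phenotypically
    heterozygous fraction is 2q(1-q) in closed form — 1/2 at equimolar
    ratio, which is why doubling the observed heterozygote count estimates
    the total number of co-integrands.
    """
    q = uptake_ratio
    if not 0.0 < q < 1.0:
        raise ValueError("uptake_ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    first = rng.random(n_draws) < q
    second = rng.random(n_draws) < q
    het = int((first != second).sum())
    frac = het / n_draws
    return {
        "heterozygous_fraction": frac,
        "closed_form": 2.0 * q * (1.0 - q),
        "n_draws": n_draws,
        "heterozygous_count": het,
        "estimated_total_cointegrands": 2 * het,
    }
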