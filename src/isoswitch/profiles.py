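"""Developmental-profile statistics: group summaries, filtering, PCA,
log-scale t-tests, ΔΔCt qPCR quantification, regional comparisons, and the
isoform-switch report.

Conventions follow common practice for small-n developmental expression
panels: group summaries are mean ± sample SD (n-1 denominator, SD reported as
0 and flagged for single-sample groups); heatmap-style filtering keeps
features whose grand-mean CPM is at or above a cutoff (default 10); PCA is
run on log2(x+1)-transformed, feature-centered data with samples as
observations and no unit-variance scaling; hypothesis tests are unpaired
two-tailed Student's t on log2(x+1) values (Welch available behind a flag);
qPCR fold changes use the 2^-ΔΔCt method against a reference gene and a
calibrator group.  No multiple-testing correction is applied by default;
Benjamini–Hochberg is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_CPM_CUTOFF = 10.0


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    df: float


def log_transform(x, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2(x + pseudocount); the transform used ahead of PCA and t-tests."""
    return np.log2(np.asarray(x, dtype=float) + pseudocount)


def group_summary(matrix: pd.DataFrame, design: Mapping[str, str]) -> pd.DataFrame:
    """Per-(feature, group) mean, sample SD (ddof=1) and n.

    ``matrix`` is features x samples; ``design`` maps each sample to a group
    label.  Single-sample groups get SD 0 with ``sd_defined`` False.
    """
    design = pd.Series(dict(design))
    missing = [s for s in design.index if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples in design absent from matrix: {missing}")
    rows = []
    for group, samples in design.groupby(design).groups.items():
        sub = matrix[list(samples)]
        n = sub.shape[1]
        if n == 0:
            raise ValueError(f"group {group} has no samples")
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if n > 1 else pd.Series(0.0, index=sub.index)
        for feature in matrix.index:
            rows.append(
                {
                    "feature": feature,
                    "group": group,
                    "mean": mean[feature],
                    "sd": sd[feature],
                    "n": n,
                    "sd_defined": n > 1,
                }
            )
    return pd.DataFrame(rows).set_index(["feature", "group"])


def filter_mean_expression(
    matrix: pd.DataFrame, cutoff: float = DEFAULT_CPM_CUTOFF
) -> pd.DataFrame:
    """Keep features whose grand mean across samples is >= cutoff (inclusive)."""
    return matrix.loc[matrix.mean(axis=1) >= cutoff]


@dataclass
class PcaResult:
    explained_variance_fractions: np.ndarray  # descending, sums to 1
    sample_scores: pd.DataFrame  # samples x components


def pca_explained_variance(
    matrix: pd.DataFrame,
    log: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PcaResult:
    """PCA over samples (observations) x features, centering only.

    Fractions are eigenvalues of the sample covariance over its trace.
    """
    from sklearn.decomposition import PCA

    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.T.to_numpy(dtype=float)  # samples x features
    if log:
        x = log_transform(x, pseudocount)
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("matrix is constant; explained variance undefined")
    pca = PCA()
    scores = pca.fit_transform(x)
    fractions = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(fractions, pd.DataFrame(scores, index=matrix.columns, columns=cols))


def log_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    already_log: bool = False,
    welch: bool = False,
) -> TestResult:
    """Unpaired two-tailed Student's t on log2-transformed expression.

    Pooled-variance (equal-variance) t with n_a + n_b - 2 degrees of freedom;
    ``welch=True`` switches to the Welch unequal-variance form.  Degenerate
    zero-variance input: equal means give t=0, p=1; unequal means are an
    error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if not already_log:
        a = log_transform(a, pseudocount)
        b = log_transform(b, pseudocount)
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return TestResult(0.0, 1.0, ma, mb, na, nb, na + nb - 2)
        raise ValueError("zero variance in both groups with unequal means")
    if welch:
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(p), float(ma), float(mb), na, nb, float(df))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (off by default in all pipelines here)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# qPCR 2^-ΔΔCt
# ---------------------------------------------------------------------------


def ddct(
    plate: pd.DataFrame,
    target_genes: Sequence[str],
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ΔΔCt method.

    ``plate`` columns: sample, group, gene, Ct.  Per sample and target:
    ΔCt = Ct_target - Ct_reference; ΔΔCt = ΔCt - mean ΔCt of the calibrator
    group; relative expression = 2^-ΔΔCt, so the calibrator group's mean
    ΔCt maps to exactly 1.
    """
    required = {"sample", "group", "gene", "Ct"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate must have columns {sorted(required)}")
    if (plate["Ct"] <= 0).any() or not np.isfinite(plate["Ct"]).all():
        raise ValueError("Ct values must be finite and positive")
    ref = plate[plate["gene"] == reference_gene].set_index("sample")["Ct"]
    rows = []
    for target in target_genes:
        tgt = plate[plate["gene"] == target]
        if tgt.empty:
            raise ValueError(f"target gene {target} absent from plate")
        missing_ref = [s for s in tgt["sample"] if s not in ref.index]
        if missing_ref:
            raise ValueError(
                f"missing reference ({reference_gene}) Ct for sample(s) "
                f"{missing_ref}"
            )
        dct = tgt.set_index("sample")["Ct"] - ref.reindex(tgt["sample"]).values
        groups = tgt.set_index("sample")["group"]
        cal = dct[groups == calibrator_group]
        if cal.empty:
            raise ValueError(f"calibrator group {calibrator_group} absent")
        ddct_vals = dct - cal.mean()
        for sample in dct.index:
            rows.append(
                {
                    "sample": sample,
                    "group": groups[sample],
                    "target": target,
                    "dct": dct[sample],
                    "ddct": ddct_vals[sample],
                    "rel_expr": 2.0 ** (-ddct_vals[sample]),
                }
            )
    return pd.DataFrame(rows)


def regional_comparison(
    matrix: pd.DataFrame,
    regions: Mapping[str, str],
    genes: Sequence[str],
    region_a: str = "superior",
    region_b: str = "inferior",
    **ttest_kwargs,
) -> pd.DataFrame:
    """Per-gene log t-test between two tissue regions, plus linear fold change.

    Models superior-vs-inferior retinal comparisons (e.g. the opposed
    dorsoventral gradients of M and S opsin).  Fold = mean(region_a) /
    mean(region_b) on the linear scale.
    """
    regions = pd.Series(dict(regions))
    sa = [s for s in matrix.columns if regions.get(s) == region_a]
    sb = [s for s in matrix.columns if regions.get(s) == region_b]
    if not sa or not sb:
        raise ValueError(f"both regions {region_a!r} and {region_b!r} required")
    rows = []
    for gene in genes:
        a = matrix.loc[gene, sa].to_numpy(dtype=float)
        b = matrix.loc[gene, sb].to_numpy(dtype=float)
        res = log_ttest(a, b, **ttest_kwargs)
        fold = a.mean() / b.mean() if b.mean() != 0 else np.inf
        rows.append(
            {
                "gene": gene,
                "t": res.t,
                "p": res.p,
                "fold": fold,
                f"mean_{region_a}": a.mean(),
                f"mean_{region_b}": b.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Switch report
# ---------------------------------------------------------------------------


def spearman(x, y) -> float:
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class SwitchReport:
    crossing_age_label: str | None
    crossing_age_t: float | None
    recovery_iso1: float | None  # Spearman(estimated iso1, true iso1)
    recovery_iso2: float | None
    whole_vs_iso1: float | None  # Spearman(whole-gene profile, true iso1)
    whole_vs_iso2: float | None
    masked: bool | None  # whole-gene correlation below self-recovery for both
    degenerate: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def switch_report(
    ages: pd.DataFrame,
    iso1_means: pd.Series,
    iso2_means: pd.Series,
    whole_means: pd.Series,
    true_iso1: pd.Series | None = None,
    true_iso2: pd.Series | None = None,
) -> SwitchReport:
    """Isoform-switch crossing age and whole-gene masking diagnostic.

    ``ages`` has columns ``age_label``/``age_t`` in panel order; the series
    are per-age group means indexed compatibly.  The crossing age is the
    first age at which the isoform-1 mean strictly exceeds the isoform-2
    mean.  When true trajectories are supplied, the masking diagnostic
    reports whether the whole-gene profile correlates (Spearman) with each
    true trajectory less well than that isoform's own estimated profile does.
    """
    if len(ages) < 3:
        raise ValueError("switch report needs >= 3 ages")
    order = ages.index
    i1 = iso1_means.reindex(order).to_numpy(dtype=float)
    i2 = iso2_means.reindex(order).to_numpy(dtype=float)
    w = whole_means.reindex(order).to_numpy(dtype=float)

    crossing_label = crossing_t = None
    above = np.nonzero(i1 > i2)[0]
    if len(above):
        crossing_label = str(ages.iloc[above[0]]["age_label"])
        crossing_t = float(ages.iloc[above[0]]["age_t"])

    degenerate = (
        np.allclose(i1, i1[0]) or np.allclose(i2, i2[0]) or np.allclose(w, w[0])
    )
    rec1 = rec2 = wv1 = wv2 = masked = None
    if true_iso1 is not None and true_iso2 is not None and not degenerate:
        t1 = true_iso1.reindex(order).to_numpy(dtype=float)
        t2 = true_iso2.reindex(order).to_numpy(dtype=float)
        rec1, rec2 = spearman(i1, t1), spearman(i2, t2)
        wv1, wv2 = spearman(w, t1), spearman(w, t2)
        masked = bool(wv1 < rec1 and wv2 < rec2)
    return SwitchReport(
        crossing_label, crossing_t, rec1, rec2, wv1, wv2, masked, degenerate
    )


def fit_late_plateau(
    ages_t: Sequence[float], means: Sequence[float]
) -> tuple[float, float, float]:
    """Least-squares fit of A/(1+exp(-(t-t50)/s)); returns (A, t50, s).

    Used to recover the sigmoid midpoint of a postnatal-rise isoform profile
    from estimated per-age means.
    """
    from scipy.optimize import curve_fit

    t = np.asarray(ages_t, dtype=float)
    y = np.asarray(means, dtype=float)

    def sigmoid(t, A, t50, s):
        return A / (1.0 + np.exp(-(t - t50) / s))

    p0 = (float(y.max()) or 1.0, float(np.median(t)), max((t.max() - t.min()) / 10, 1.0))
    popt, _ = curve_fit(sigmoid, t, y, p0=p0, maxfev=20000)
    A, t50, s = (float(v) for v in popt)
    return A, t50, abs(s)
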