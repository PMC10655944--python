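"""Multivariate statistics on superimposed shape coordinates.

Principal component analysis of the covariance matrix of Procrustes tangent
coordinates yields uncorrelated shape variables; score matrices from several
cranial views can be column-joined and re-decomposed to pool dorsal, ventral
and lateral information.  Group differences in shape are tested with Wilks'
lambda MANOVA (one-way, pairwise with Bonferroni correction, and two-factor
with interaction); size differences with one-way ANOVA plus Tukey-Kramer
multiple comparisons.

Wilks' lambda is det(W)/det(W+B) for within- and between-group SSCP matrices;
small values indicate strong separation.  F statistics and degrees of freedom
use Rao's approximation, which is exact for two groups or up to two response
variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SingularCovarianceError(np.linalg.LinAlgError):
    """Within-group SSCP is singular; reduce the number of PCs."""


@dataclass
class ShapeSpace:
    """A principal-component decomposition of shape variables.

    ``eigenvectors`` is p x d (columns are components), ``scores`` n x d with
    zero column means, ``eigenvalues`` the descending sample variances along
    each component, and ``mean`` the 1 x p centroid needed to reconstruct the
    input as ``scores @ eigenvectors.T + mean``.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    source_view: str = "unknown"
    ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def d(self) -> int:
        return self.eigenvalues.size

    @property
    def variance_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def n_components_for(self, frac: float) -> int:
        """Smallest number of leading PCs explaining >= ``frac`` of variance."""
        cum = np.cumsum(self.variance_explained)
        return int(np.searchsorted(cum, frac - 1e-12) + 1)

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.eigenvectors.T + self.mean


@dataclass(frozen=True)
class ManovaResult:
    """One Wilks' lambda test: term label, lambda, Rao F, dfs and p-value."""

    term: str
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.wilks_lambda <= 1.0 + 1e-9:
            raise ValueError(f"Wilks lambda {self.wilks_lambda} outside [0,1]")


def shape_pca(tangent: np.ndarray, source_view: str = "unknown",
              ids: Sequence[str] = ()) -> ShapeSpace:
    """PCA of the sample covariance matrix (divisor n - 1) of shape variables.

    Components with eigenvalue below 1e-12 times the largest are dropped
    (GPA tangent data have at least four null directions: two translations,
    rotation and scale).  Eigenvector signs follow a fixed convention — the
    largest-magnitude loading of each component is positive — so results are
    reproducible across runs and platforms.
    """
    x = np.asarray(tangent, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0, keepdims=True)
    centred = x - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    keep = eigenvalues > 1e-12 * (eigenvalues[0] if eigenvalues.size else 0.0)
    eigenvalues = eigenvalues[keep]
    vecs = vt[keep].T
    scores = centred @ vecs
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
            scores[:, j] = -scores[:, j]
    return ShapeSpace(
        eigenvectors=vecs,
        eigenvalues=eigenvalues,
        scores=scores,
        mean=mean,
        source_view=source_view,
        ids=tuple(ids),
    )


def join_views(spaces: Sequence[ShapeSpace]) -> ShapeSpace:
    """Pool several views into one integrated shape space.

    The per-view PC score matrices are column-concatenated (specimens must
    match in identity and order) and the joined matrix is decomposed again;
    total variance is conserved because each score matrix already has
    orthogonal columns.
    """
    if not spaces:
        raise ValueError("no shape spaces to join")
    ref_ids = spaces[0].ids
    for sp in spaces[1:]:
        if sp.ids != ref_ids:
            extra = set(sp.ids) ^ set(ref_ids)
            raise ValueError(
                "specimen sets/order differ between views"
                + (f"; mismatched ids: {sorted(extra)}" if extra else
                   " (same ids, different order)")
            )
        if sp.scores.shape[0] != spaces[0].scores.shape[0]:
            raise ValueError("specimen counts differ between views")
    joined = np.hstack([sp.scores for sp in spaces])
    out = shape_pca(joined, source_view="integrated", ids=ref_ids)
    return out


def _sscp_within_between(x: np.ndarray,
                         labels: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                      int]:
    groups = np.unique(labels)
    grand = x.mean(axis=0)
    d = x.shape[1]
    w = np.zeros((d, d))
    b = np.zeros((d, d))
    for g in groups:
        xg = x[labels == g]
        if xg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        mg = xg.mean(axis=0)
        r = xg - mg
        w += r.T @ r
        dm = (mg - grand)[:, None]
        b += xg.shape[0] * (dm @ dm.T)
    return w, b, groups.size


def _rao_f(lam: float, d: int, q: int, v: int, term: str) -> ManovaResult:
    # Rao's F approximation for Wilks' lambda with d response variables,
    # q hypothesis df and v error df.
    denom = d * d + q * q - 5
    t = np.sqrt((d * d * q * q - 4) / denom) if denom > 0 else 1.0
    w = v + q - (d + q + 1) / 2.0
    df1 = float(d * q)
    df2 = w * t - (d * q - 2) / 2.0
    if df2 <= 0:
        raise SingularCovarianceError(
            f"term {term!r}: error df too small for {d} response variables; "
            "reduce the number of PCs"
        )
    lam = min(max(lam, 0.0), 1.0)
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ManovaResult(term=term, wilks_lambda=float(lam), F=float(F),
                        df1=df1, df2=df2, p=p)


def _wilks(w: np.ndarray, b: np.ndarray, term: str) -> float:
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularCovarianceError(
            f"term {term!r}: singular within-group SSCP; reduce the number "
            "of PCs"
        )
    return float(np.exp(logdet_w - logdet_t))


def wilks_manova(scores: np.ndarray, labels: Sequence,
                 term: str = "group") -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    Requires every group to have at least two members and the response
    dimension not to exceed the error degrees of freedom.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    labels = np.asarray(labels)
    if labels.size != x.shape[0]:
        raise ValueError("labels length must match rows of scores")
    w, b, g = _sscp_within_between(x, labels)
    if g < 2:
        raise ValueError("need at least two groups")
    lam = _wilks(w, b, term)
    return _rao_f(lam, d=x.shape[1], q=g - 1, v=x.shape[0] - g, term=term)


def pairwise_manova(scores: np.ndarray, labels: Sequence,
                    alpha: float = 0.05,
                    auto_reduce: bool = True) -> pd.DataFrame:
    """Wilks' lambda MANOVA for every unordered pair of groups.

    Significance flags use the Bonferroni correction: a pair is flagged iff
    its p-value is below ``alpha`` divided by the number of pairs.  With
    ``auto_reduce`` the response columns (assumed variance-ordered PCs) are
    truncated per pair to at most ``n_pair - 3`` so small groups keep a
    nonsingular within-group SSCP; the number of columns used is reported.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    groups = sorted(map(str, np.unique(labels)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(groups, 2))
    threshold = alpha / len(pairs)
    rows = []
    for a, b in pairs:
        mask = np.isin(labels.astype(str), (a, b))
        xs, ls = x[mask], labels[mask]
        d_use = x.shape[1]
        if auto_reduce:
            d_use = min(d_use, max(1, xs.shape[0] - 3))
        res = wilks_manova(xs[:, :d_use], ls, term=f"{a} x {b}")
        rows.append({
            "group_a": a, "group_b": b, "n": int(mask.sum()),
            "d_used": d_use, "wilks_lambda": res.wilks_lambda,
            "F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p,
            "significant": res.p < threshold,
        })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_comparisons"] = len(pairs)
    return out


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def _residual_sscp(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return r.T @ r, int(np.linalg.matrix_rank(x))


def factorial_manova(scores: np.ndarray, factor_a: Sequence,
                     factor_b: Sequence,
                     names: tuple[str, str] = ("A", "B")) -> list[ManovaResult]:
    """Two-factor MANOVA with interaction, Type II sums of squares.

    Type II tests each main effect adjusted for the other main effect (but
    not the interaction), the standard choice for unbalanced designs; the
    interaction is tested against the full-model residual.  A factor with a
    single level is dropped (together with the interaction), so the result
    degenerates to the one-way test on the other factor.
    """
    y = np.atleast_2d(np.asarray(scores, dtype=float))
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    n = y.shape[0]
    if fa.size != n or fb.size != n:
        raise ValueError("factor lengths must match rows of scores")
    a_levels, b_levels = np.unique(fa), np.unique(fb)
    if a_levels.size < 2 and b_levels.size < 2:
        raise ValueError("both factors are constant")
    if a_levels.size < 2:
        return [wilks_manova(y, fb, term=names[1])]
    if b_levels.size < 2:
        return [wilks_manova(y, fa, term=names[0])]

    cells = pd.crosstab(fa, fb).to_numpy()
    if (cells == 0).any():
        raise ValueError(
            f"empty factor crossing: interaction {names[0]}:{names[1]} "
            "is inestimable"
        )
    if (cells >= 2).sum() == 0:
        raise ValueError(
            f"interaction {names[0]}:{names[1]} untestable: no cell has "
            ">= 2 observations"
        )

    ones = np.ones((n, 1))
    da, db = _dummy(fa), _dummy(fb)
    dab = np.hstack([da[:, [i]] * db[:, [j]]
                     for i in range(da.shape[1])
                     for j in range(db.shape[1])])
    e_full, rank_full = _residual_sscp(y, np.hstack([ones, da, db, dab]))
    e_add, _ = _residual_sscp(y, np.hstack([ones, da, db]))
    e_no_a, _ = _residual_sscp(y, np.hstack([ones, db]))
    e_no_b, _ = _residual_sscp(y, np.hstack([ones, da]))

    v = n - rank_full
    d = y.shape[1]
    results = []
    for term, h, q in (
        (names[0], e_no_a - e_add, a_levels.size - 1),
        (names[1], e_no_b - e_add, b_levels.size - 1),
        (f"{names[0]}:{names[1]}", e_add - e_full,
         (a_levels.size - 1) * (b_levels.size - 1)),
    ):
        lam = _wilks(e_full, h, term)
        results.append(_rao_f(lam, d=d, q=q, v=v, term=term))
    return results


def anova_tukey(values: Sequence[float], labels: Sequence,
                ) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey-Kramer honest significant differences.

    Returns the ANOVA F and p plus a table of all pairwise comparisons with
    mean differences and studentized-range p-values (the Tukey-Kramer form
    handles unequal group sizes).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(map(str, np.unique(labels)))
    samples = [values[labels.astype(str) == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 members")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        rows.append({
            "group_a": groups[i], "group_b": groups[j],
            "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
            "p_adj": float(tk.pvalue[i, j]),
            "significant": bool(tk.pvalue[i, j] < 0.05),
        })
    return float(F), float(p), pd.DataFrame(rows)
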