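"""Linear discriminant analysis of shape variables with cross-validation.

Group separation in shape space is summarised by canonical discriminant axes
(eigenvectors of the between-group SSCP in the pooled within-group metric) and
quantified by leave-one-out cross-validated classification: each specimen is
classified by a discriminant model fitted to all other specimens, giving an
unbiased estimate of the correct-classification percentage.  Because tangent
dimensionality exceeds group sizes, LDA runs on principal-component scores;
the subset of PCs entering the model is chosen to maximise overall LOOCV
accuracy, by forward selection (default) or exhaustive enumeration.

Priors are equal by default: group sample sizes reflect collecting effort,
not prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .shape_stats import SingularCovarianceError


@dataclass
class LdaModel:
    """Fitted linear discriminant model with canonical axes."""

    groups: tuple[str, ...]
    group_means: np.ndarray          # g x d
    pooled_covariance: np.ndarray    # d x d
    discriminant_axes: np.ndarray    # d x r, r = min(g-1, d)
    axis_variance_explained: np.ndarray
    priors: np.ndarray
    n: int

    @property
    def r(self) -> int:
        return self.discriminant_axes.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project observations onto the canonical discriminant axes."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        centre = self.group_means.mean(axis=0)
        return (x - centre) @ self.discriminant_axes

    def _sq_mahalanobis(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diff = x[:, None, :] - self.group_means[None, :, :]   # n x g x d
        solved = np.linalg.solve(
            self.pooled_covariance, diff.reshape(-1, diff.shape[-1]).T
        ).T.reshape(diff.shape)
        return np.einsum("ngd,ngd->ng", diff, solved)

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Group-membership probabilities (equal-covariance Gaussian model)."""
        log_p = -0.5 * self._sq_mahalanobis(x) + np.log(self.priors)
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=1, keepdims=True)

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Assign each observation to the nearest group (Mahalanobis metric,
        adjusted for priors)."""
        score = -0.5 * self._sq_mahalanobis(x) + np.log(self.priors)
        return np.array([self.groups[i] for i in np.argmax(score, axis=1)])


@dataclass
class CvReport:
    """Aggregated leave-one-out cross-validation results."""

    groups: tuple[str, ...]
    confusion: np.ndarray            # g x g counts, rows = true group
    posteriors: pd.DataFrame         # per-specimen membership probabilities
    n_failed_folds: int = 0

    @property
    def per_group_pct(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0,
                            np.diag(self.confusion) / totals, np.nan)

    @property
    def overall_pct(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.groups),
                            columns=list(self.groups))


def _check_xy(scores, labels):
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1 and np.asarray(labels).size > 1:
        x = x.T
    y = np.asarray(labels).astype(str)
    if y.size != x.shape[0]:
        raise ValueError("labels length must match rows of scores")
    return x, y


def lda_fit(scores: np.ndarray, labels: Sequence,
            priors: Sequence[float] | None = None) -> LdaModel:
    """Fit canonical LDA: axes of maximal between/within variance ratio.

    Axes solve the generalized eigenproblem B a = lambda W a (between vs
    pooled within-group SSCP), are scaled to unit pooled-within variance
    (a' S a = 1) and sign-fixed so the largest-magnitude loading is positive.
    At most min(g - 1, d) axes carry signal and are retained.
    """
    x, y = _check_xy(scores, labels)
    n, d = x.shape
    groups = tuple(sorted(set(y)))
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    means = np.stack([x[y == grp].mean(axis=0) for grp in groups])
    w = np.zeros((d, d))
    for grp, m in zip(groups, means):
        r = x[y == grp] - m
        if r.shape[0] < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 members")
        w += r.T @ r
    pooled = w / (n - g)
    grand = x.mean(axis=0)
    b = np.zeros((d, d))
    for grp, m in zip(groups, means):
        dm = (m - grand)[:, None]
        b += (y == grp).sum() * (dm @ dm.T)
    try:
        chol = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            "singular pooled covariance; use fewer PCs"
        ) from None
    li = np.linalg.inv(chol)
    sym = li @ b @ li.T
    eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    r = min(g - 1, d)
    eigval = np.clip(eigval[order[:r]], 0.0, None)
    axes = li.T @ eigvec[:, order[:r]]
    for j in range(axes.shape[1]):
        if axes[np.argmax(np.abs(axes[:, j])), j] < 0:
            axes[:, j] = -axes[:, j]
    total = eigval.sum()
    var_expl = eigval / total if total > 0 else np.zeros_like(eigval)
    if priors is None:
        pr = np.full(g, 1.0 / g)
    else:
        pr = np.asarray(priors, dtype=float)
        pr = pr / pr.sum()
    return LdaModel(groups=groups, group_means=means,
                    pooled_covariance=pooled, discriminant_axes=axes,
                    axis_variance_explained=var_expl, priors=pr, n=n)


def resubstitution_report(scores, labels,
                          priors: Sequence[float] | None = None) -> CvReport:
    """Classify the training data with the model fitted on all of it."""
    x, y = _check_xy(scores, labels)
    model = lda_fit(x, y, priors=priors)
    return _build_report(model.groups, y, model.classify(x),
                         model.posterior(x), ids=None)


def _build_report(groups, true, predicted, posteriors, ids,
                  n_failed: int = 0) -> CvReport:
    gidx = {g: i for i, g in enumerate(groups)}
    confusion = np.zeros((len(groups), len(groups)), dtype=int)
    for t, p in zip(true, predicted):
        confusion[gidx[t], gidx[p]] += 1
    post = pd.DataFrame(posteriors, columns=list(groups))
    post.insert(0, "true_group", list(true))
    post.insert(1, "predicted_group", list(predicted))
    if ids is not None:
        post.insert(0, "specimen_id", list(ids))
    return CvReport(groups=tuple(groups), confusion=confusion,
                    posteriors=post, n_failed_folds=n_failed)


def loocv_classify(scores, labels, priors: Sequence[float] | None = None,
                   ids: Sequence[str] | None = None) -> CvReport:
    """Leave-one-out cross-validated classification.

    Each specimen is held out in turn, the discriminant model refitted on the
    rest, and the held-out specimen assigned to the nearest group in that
    model's Mahalanobis metric.  Folds whose refit is degenerate (a group
    reduced below two members, or a singular covariance) are skipped with a
    warning and excluded from the report.
    """
    x, y = _check_xy(scores, labels)
    groups = tuple(sorted(set(y)))
    kept_true, kept_pred, kept_post, kept_ids = [], [], [], []
    n_failed = 0
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        try:
            model = lda_fit(x[mask], y[mask], priors=priors)
        except (ValueError, np.linalg.LinAlgError) as e:
            n_failed += 1
            warnings.warn(f"LOOCV fold {i} skipped: {e}", RuntimeWarning)
            continue
        kept_true.append(y[i])
        kept_pred.append(model.classify(x[i:i + 1])[0])
        post = np.zeros(len(groups))
        pf = model.posterior(x[i:i + 1])[0]
        for gname, val in zip(model.groups, pf):
            post[groups.index(gname)] = val
        kept_post.append(post)
        kept_ids.append(ids[i] if ids is not None else str(i))
    if not kept_true:
        raise ValueError("every LOOCV fold failed")
    return _build_report(groups, kept_true, kept_pred,
                         np.stack(kept_post), kept_ids, n_failed=n_failed)


def select_pc_subset(scores, labels, strategy: str = "forward",
                     max_pcs: int | None = None,
                     priors: Sequence[float] | None = None,
                     ) -> tuple[tuple[int, ...], CvReport]:
    """Choose the PC subset maximising overall LOOCV accuracy.

    ``strategy='exhaustive'`` evaluates every combination of up to
    ``max_pcs`` columns (feasible for d of a dozen or so); ``'forward'``
    greedily adds the best single PC per step and finally compares against
    the full candidate set, so the returned subset never scores below it.
    Ties prefer fewer PCs, then the lexicographically smallest index set.
    Returns the winning 0-based column indices and their LOOCV report.
    """
    x, y = _check_xy(scores, labels)
    d = x.shape[1]
    if max_pcs is None:
        max_pcs = d
    if not 1 <= max_pcs <= d:
        raise ValueError(f"max_pcs must be in 1..{d}")

    cache: dict[tuple[int, ...], CvReport] = {}

    def evaluate(subset: tuple[int, ...]) -> CvReport | None:
        if subset not in cache:
            try:
                cache[subset] = loocv_classify(x[:, list(subset)], y,
                                               priors=priors)
            except (ValueError, np.linalg.LinAlgError):
                return None
        return cache[subset]

    def better(cand: tuple[int, ...], acc: float,
               best: tuple[int, ...] | None, best_acc: float) -> bool:
        if best is None or acc > best_acc + 1e-12:
            return True
        if acc < best_acc - 1e-12:
            return False
        return (len(cand), cand) < (len(best), best)

    best: tuple[int, ...] | None = None
    best_acc = -1.0
    if strategy == "exhaustive":
        for size in range(1, max_pcs + 1):
            for comb in combinations(range(d), size):
                rep = evaluate(comb)
                if rep is not None and better(comb, rep.overall_pct,
                                              best, best_acc):
                    best, best_acc = comb, rep.overall_pct
    elif strategy == "forward":
        current: tuple[int, ...] = ()
        current_acc = -1.0
        while len(current) < max_pcs:
            step_best, step_acc = None, -1.0
            for j in range(d):
                if j in current:
                    continue
                cand = tuple(sorted(current + (j,)))
                rep = evaluate(cand)
                if rep is None:
                    continue
                if rep.overall_pct > step_acc + 1e-12 or (
                    abs(rep.overall_pct - step_acc) <= 1e-12
                    and (step_best is None or cand < step_best)
                ):
                    step_best, step_acc = cand, rep.overall_pct
            if step_best is None or step_acc <= current_acc + 1e-12:
                break
            current, current_acc = step_best, step_acc
            if better(current, current_acc, best, best_acc):
                best, best_acc = current, current_acc
        full = tuple(range(d))
        if len(full) <= max_pcs:
            rep = evaluate(full)
            if rep is not None and rep.overall_pct > best_acc + 1e-12:
                best, best_acc = full, rep.overall_pct
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if best is None:
        raise ValueError("no evaluable PC subset found")
    return best, cache[best]
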