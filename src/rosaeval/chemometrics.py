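"""Multivariate chemometrics for the stage-wise volatile survey.

Covers the workhorse core of targeted/untargeted flavor
metabolomics: unit-variance scaling, PCA with per-component contribution
rates, two-class OPLS-DA with the S-plot and VIP statistic, fold-change
computation with a pseudo-value rule for undetected compounds, and the
joint VIP/fold-change differential screen applied to consecutive
flower-development stages of each cultivar.

OPLS-DA here is the single-response (PLS1) formulation: the class label is
coded +/-1 and centered, variation in X orthogonal to y is peeled off one
component at a time (orthogonal signal correction), and one predictive PLS
component is fitted on the filtered X. With zero orthogonal components the
model reduces exactly to the first component of PLS1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError

#: GC-MS vial codes of the four flower-development stages (bud .. withering).
STAGE_CODE = {1: 1, 2: 3, 3: 5, 4: 7}


# ---------------------------------------------------------------------------
# scaling and PCA


@dataclass(frozen=True)
class ScaledMatrix:
    """Unit-variance-scaled data with the scaling parameters retained."""

    data: np.ndarray  # samples x variables, each column mean 0 / sd 1
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance columns
    columns: tuple[str, ...] = ()


def uv_scale(matrix, columns: tuple[str, ...] = ()) -> ScaledMatrix:
    """Column-wise (x - mean) / sd with the sample sd (n-1 denominator).

    Zero-variance columns cannot be scaled; they are set to all-zero and
    flagged in ``constant``.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = tuple(matrix.columns)
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("unit-variance scaling needs at least two samples")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    scaled = (x - mean) / safe_sd
    scaled[:, constant] = 0.0
    return ScaledMatrix(data=scaled, mean=mean, sd=sd, constant=constant, columns=columns)


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and contribution rates of a PCA."""

    scores: np.ndarray  # samples x A
    loadings: np.ndarray  # variables x A
    contribution: np.ndarray  # % of total variance per returned component
    all_contribution: np.ndarray  # % for every component up to min(n-1, p)


def pca(scaled: ScaledMatrix, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA of an already-scaled matrix.

    The contribution rate of component ``a`` is ``100 lambda_a / sum
    lambda``, the familiar percentage of explained variance; rates over
    all ``min(n-1, p)`` components sum to 100.
    """
    x = scaled.data
    n, p = x.shape
    max_a = min(n - 1, p)
    a = max_a if n_components is None else int(n_components)
    if not 1 <= a <= max_a:
        raise ValidationError(f"n_components must be in [1, {max_a}] for a {n}x{p} matrix")
    u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    lam = s**2
    total = lam[:max_a].sum()
    if total == 0:
        raise ValidationError("matrix has no variance; PCA is undefined")
    rates = 100.0 * lam[:max_a] / total
    return PCAResult(
        scores=u[:, :a] * s[:a],
        loadings=vt[:a].T,
        contribution=rates[:a],
        all_contribution=rates,
    )


def combined_contribution(rates, k: int = 2) -> float:
    """Combined contribution rate (%) of the first ``k`` components."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) < k:
        raise ValidationError(f"need at least {k} component rates")
    return float(rates[:k].sum())


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass(frozen=True)
class OPLSDAModel:
    """Two-class OPLS-DA fit (one predictive component).

    ``t, w, p`` are the predictive score, weight and loading vectors;
    ``t_orth, w_orth, p_orth`` stack the orthogonal components row-wise.
    ``classes`` maps the two labels to the -1/+1 coding of ``y``.
    """

    t: np.ndarray
    w: np.ndarray
    p: np.ndarray
    c: float  # y-loading of the predictive component
    t_orth: np.ndarray  # n_orth x samples
    w_orth: np.ndarray  # n_orth x variables
    p_orth: np.ndarray  # n_orth x variables
    y: np.ndarray  # centered +/-1 coding
    x_filtered: np.ndarray  # X after orthogonal signal removal
    x_original: np.ndarray
    r2x: float
    r2y: float
    classes: tuple = ()
    columns: tuple[str, ...] = ()
    constant: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def fit_oplsda(scaled: ScaledMatrix, labels, n_orth: int = 1) -> OPLSDAModel:
    """Fit a two-class OPLS-DA model on a UV-scaled matrix.

    Labels are coded -1 (first class in sorted order) / +1 and centered.
    Each orthogonal component is built from the y-orthogonalized part of
    the predictive loading and deflated from X; the single predictive PLS
    component is then fitted on the filtered matrix.
    """
    x = scaled.data.copy()
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels).tolist()))
    if len(classes) != 2:
        raise ValidationError(f"OPLS-DA needs exactly two classes, got {classes}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValidationError("each class needs at least two samples")
    y = np.where(labels == classes[1], 1.0, -1.0)
    y = y - y.mean()
    rank = np.linalg.matrix_rank(x)
    if n_orth < 0:
        raise ValidationError("n_orth must be >= 0")
    if n_orth >= rank:
        raise RangeError(f"n_orth={n_orth} must be below rank(X)={rank}")

    x0 = x.copy()
    t_os, w_os, p_os = [], [], []
    for _ in range(n_orth):
        w = x.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = x @ w
        p = x.T @ t / (t @ t)
        w_o = p - (w @ p) / (w @ w) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o /= nrm
        t_o = x @ w_o
        p_o = x.T @ t_o / (t_o @ t_o)
        x = x - np.outer(t_o, p_o)
        t_os.append(t_o)
        w_os.append(w_o)
        p_os.append(p_o)

    w = x.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = x @ w
    p = x.T @ t / (t @ t)
    c = float(y @ t / (t @ t))

    ssx = float((x0**2).sum())
    explained = float((np.outer(t, p) ** 2).sum()) + sum(
        float((np.outer(t_o, p_o) ** 2).sum()) for t_o, p_o in zip(t_os, p_os)
    )
    r2y = 1.0 - float(((y - c * t) ** 2).sum() / (y @ y))
    stack = lambda vs, width: np.array(vs).reshape(len(vs), width) if vs else np.zeros((0, width))
    return OPLSDAModel(
        t=t,
        w=w,
        p=p,
        c=c,
        t_orth=stack(t_os, len(t)),
        w_orth=stack(w_os, len(w)),
        p_orth=stack(p_os, len(w)),
        y=y,
        x_filtered=x,
        x_original=x0,
        r2x=explained / ssx if ssx > 0 else 0.0,
        r2y=r2y,
        classes=classes,
        columns=scaled.columns,
        constant=scaled.constant,
    )


def vip(model: OPLSDAModel, mode: str = "predictive") -> np.ndarray:
    """Variable importance in projection.

    ``mode='predictive'`` (default) scores variables on the predictive
    component only — the component that carries the class separation — so
    ``VIP_j = sqrt(p) |w_j| / ||w||`` and the mean squared VIP is exactly
    1 (``sum VIP^2 = p``). ``mode='total'`` additionally weighs the
    orthogonal weight vectors by their explained X variation; the same
    normalization identity holds because each weight vector has unit norm
    and the weights are convex.
    """
    p_vars = len(model.w)
    ssy = float((model.c * model.t) @ (model.c * model.t))
    if mode == "predictive" or model.w_orth.shape[0] == 0:
        frac = (model.w / np.linalg.norm(model.w)) ** 2
        return np.sqrt(p_vars * frac)
    if mode != "total":
        raise ValidationError(f"unknown VIP mode {mode!r}")
    ssx_o = [float((np.outer(t_o, p_o) ** 2).sum()) for t_o, p_o in zip(model.t_orth, model.p_orth)]
    weights = np.array([ssy] + ssx_o)
    weights = weights / weights.sum()
    vecs = np.vstack([model.w / np.linalg.norm(model.w), model.w_orth])
    return np.sqrt(p_vars * (weights[:, None] * vecs**2).sum(axis=0))


def s_plot(model: OPLSDAModel) -> pd.DataFrame:
    """Per-variable S-plot coordinates against the predictive score.

    ``p1`` is the covariance and ``pcorr1`` the correlation of each
    variable with ``t``; variables with zero variance get ``pcorr1 = 0``
    and are flagged.
    """
    t = model.t
    x = model.x_original
    n = len(t)
    p1 = (x - x.mean(axis=0)).T @ (t - t.mean()) / (n - 1)
    sd_x = x.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    degenerate = (sd_x == 0) | (sd_t == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcorr1 = np.where(degenerate, 0.0, p1 / (np.where(degenerate, 1.0, sd_x) * sd_t))
    cols = model.columns if model.columns else tuple(range(x.shape[1]))
    return pd.DataFrame({"variable": cols, "p1": p1, "pcorr1": pcorr1, "degenerate": degenerate})


# ---------------------------------------------------------------------------
# fold change and the differential screen


def fold_change_table(later: pd.DataFrame, earlier: pd.DataFrame) -> pd.DataFrame:
    """Per-compound fold change between two replicate groups.

    ``later`` and ``earlier`` are replicate x compound tables of one
    comparison. FC = mean(later) / mean(earlier). Zero group means are
    replaced by half the smallest positive group mean in the comparison
    (a pseudo-value keeping FC finite, as undetected compounds are true
    zeros); compounds with both means zero are flagged undefined.
    """
    if later.empty or earlier.empty:
        raise ValidationError("both groups must be non-empty")
    if list(later.columns) != list(earlier.columns):
        raise ValidationError("group tables must share the same compound columns")
    m_later = later.mean(axis=0).to_numpy(dtype=float)
    m_earlier = earlier.mean(axis=0).to_numpy(dtype=float)
    positive = np.concatenate([m_later[m_later > 0], m_earlier[m_earlier > 0]])
    undefined = (m_later == 0) & (m_earlier == 0)
    if positive.size == 0:
        raise ValidationError("all group means are zero; fold change undefined everywhere")
    pseudo = 0.5 * positive.min()
    ml = np.where(m_later == 0, pseudo, m_later)
    me = np.where(m_earlier == 0, pseudo, m_earlier)
    fc = ml / me
    out = pd.DataFrame(
        {
            "compound": later.columns,
            "mean_later": m_later,
            "mean_earlier": m_earlier,
            "FC": np.where(undefined, np.nan, fc),
            "log2FC": np.where(undefined, np.nan, np.log2(fc)),
            "undefined": undefined,
        }
    )
    return out


def screen_differential(vip_values, fold_changes) -> pd.DataFrame:
    """Joint VIP / fold-change screen.

    A compound is ``up`` when VIP > 1 and FC >= 2, ``down`` when VIP > 1
    and FC <= 0.5, else ``not_significant``. Compounds with undefined FC
    are excluded (status ``excluded``). Volcano coordinates (log2FC, VIP)
    are included for plotting.
    """
    vip_values = pd.Series(vip_values)
    fc = fold_changes if isinstance(fold_changes, pd.DataFrame) else pd.DataFrame(
        {"compound": vip_values.index, "FC": np.asarray(fold_changes, dtype=float)}
    )
    if len(vip_values) != len(fc):
        raise ValidationError("VIP and fold-change lists have different lengths")
    fc = fc.reset_index(drop=True)
    v = vip_values.to_numpy(dtype=float)
    f = fc["FC"].to_numpy(dtype=float)
    undefined = np.isnan(f)
    status = np.where(
        undefined,
        "excluded",
        np.where((v > 1) & (f >= 2), "up", np.where((v > 1) & (f <= 0.5), "down", "not_significant")),
    )
    out = fc.copy()
    out["VIP"] = v
    if "log2FC" not in out.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log2FC"] = np.log2(f)
    out["status"] = status
    return out[["compound", "VIP", "FC", "log2FC", "status"] + [c for c in out.columns if c in ("mean_later", "mean_earlier", "undefined")]]


# ---------------------------------------------------------------------------
# stage-wise pipeline over a long-format survey


def stage_matrix(voc: pd.DataFrame, cultivar: str, stage: int) -> pd.DataFrame:
    """Replicate x compound matrix of one (cultivar, stage) cell."""
    cell = voc[(voc["cultivar"] == cultivar) & (voc["stage"] == stage)]
    if cell.empty:
        raise ValidationError(f"no records for cultivar {cultivar!r} at stage {stage}")
    return cell.pivot_table(index="replicate", columns="compound", values="concentration", sort=True)


def compare_stages(
    voc: pd.DataFrame, cultivar: str, earlier: int, later: int, n_orth: int = 1
) -> pd.DataFrame:
    """Differential screen of one stage pair of one cultivar.

    Replicates of the two stages are stacked, UV-scaled, modelled with
    OPLS-DA (earlier vs later), and compounds are screened with
    VIP > 1 and FC >= 2 / <= 0.5 (FC oriented later / earlier).
    """
    a = stage_matrix(voc, cultivar, earlier)
    b = stage_matrix(voc, cultivar, later)
    b = b[a.columns]
    x = pd.concat([a, b], axis=0)
    labels = np.array(["earlier"] * len(a) + ["later"] * len(b))
    scaled = uv_scale(x)
    model = fit_oplsda(scaled, labels, n_orth=n_orth)
    vips = pd.Series(vip(model), index=scaled.columns)
    fc = fold_change_table(b, a)
    result = screen_differential(vips.to_numpy(), fc)
    result.insert(0, "comparison", f"{cultivar}{STAGE_CODE[earlier]}_vs_{cultivar}{STAGE_CODE[later]}")
    return result


def consecutive_stage_screen(voc: pd.DataFrame, n_orth: int = 1) -> pd.DataFrame:
    """All consecutive-stage comparisons of every cultivar (nine for the
    default three-cultivar, four-stage survey), concatenated."""
    frames = []
    for cultivar in sorted(voc["cultivar"].unique()):
        stages = sorted(voc.loc[voc["cultivar"] == cultivar, "stage"].unique())
        for s1, s2 in zip(stages, stages[1:]):
            frames.append(compare_stages(voc, cultivar, int(s1), int(s2), n_orth=n_orth))
    if not frames:
        raise ValidationError("no comparable stage pairs in the survey")
    return pd.concat(frames, ignore_index=True)


def differential_union(screen: pd.DataFrame) -> list[str]:
    """Set union of differential compound names over all comparisons."""
    mask = screen["status"].isin(["up", "down"])
    return sorted(screen.loc[mask, "compound"].unique().tolist())
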