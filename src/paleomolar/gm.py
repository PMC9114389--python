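"""Landmark/semilandmark geometric morphometrics of the enamel-dentine
junction (EDJ).

The crown template has 94 points: 4 anatomical landmarks on the dentine
horns (protoconid, metaconid, entoconid, hypoconid), 60 semilandmarks
along the marginal ridge connecting them (segments of 12/12/24/12 interior
points, running protoconid -> metaconid -> entoconid -> hypoconid ->
protoconid, i.e. starting at the protoconid and moving lingually), and 30
equally spaced semilandmarks along the cervix starting below the
protoconid and moving mesially.  Curves are interpolated with cubic
splines and resampled at equal arc-length spacing (no bending-energy
sliding).

Shape analysis: generalised Procrustes alignment (translation, unit
centroid size, optimal rotation, iterated mean), tangent-space PCA,
between-group PCA (PCA of the equally weighted group means), canonical
variate analysis on a reduced PC basis, leave-one-out cross-validated
classification, strict a-posteriori projection of unknowns, and
permutation tests of allometry (score on centroid size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.interpolate import CubicSpline

from .core import ValidationError

__all__ = [
    "LandmarkConfig", "ShapeSpace", "OrdinationResult", "Classification",
    "HORN_ORDER", "RIDGE_SEGMENT_COUNTS", "N_TEMPLATE", "resample_curve",
    "build_template", "gpa", "pca", "select_pcs", "bgpca", "cva",
    "cross_validate", "allometry_regression", "read_tps", "write_tps",
    "read_landmarks_csv",
]

HORN_ORDER = ("protoconid", "metaconid", "entoconid", "hypoconid")
#: interior semilandmarks per marginal-ridge segment (horn-to-horn)
RIDGE_SEGMENT_COUNTS = (12, 12, 24, 12)
N_ANATOMICAL = 4
N_RIDGE = sum(RIDGE_SEGMENT_COUNTS)
N_CERVIX = 30
N_TEMPLATE = N_ANATOMICAL + N_RIDGE + N_CERVIX     # 94


@dataclass
class LandmarkConfig:
    """One specimen's landmark configuration (template order, k x 3 mm)."""

    coords: np.ndarray
    label: str = ""
    group: str | None = None
    mirrored: bool = False
    n_points: int = N_TEMPLATE

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (k, 3)")
        if self.coords.shape[0] != self.n_points:
            raise ValidationError(
                f"expected {self.n_points} points, got {self.coords.shape[0]}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")

    @property
    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c ** 2).sum()))


@dataclass
class ShapeSpace:
    """Procrustes-aligned sample: (n, k, 3) coordinates at unit centroid
    size, the converged mean shape and the original centroid sizes."""

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    labels: list[str]
    groups: list[str | None]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    def tangent_coords(self) -> np.ndarray:
        """Tangent-space coordinates: flattened aligned shapes, centred on
        the mean and orthogonally projected at the mean."""
        x = self.aligned.reshape(self.n, -1)
        m = self.mean_shape.reshape(-1)
        m_hat = m / np.linalg.norm(m)
        xc = x - m
        return xc - np.outer(xc @ m_hat, m_hat)


@dataclass
class OrdinationResult:
    """Scores on ordination axes plus the pieces needed to project new
    specimens a posteriori."""

    scores: np.ndarray
    axes: np.ndarray                  # (k_axes, p), rows are axes
    explained: np.ndarray
    kind: str
    center: np.ndarray
    groups: list[str | None] | None = None
    group_mean_scores: dict[str, np.ndarray] | None = None
    unknown_scores: np.ndarray | None = None
    classification: "Classification | None" = None

    def project(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return (x - self.center) @ self.axes.T


@dataclass
class Classification:
    predicted: list[str]
    posterior: pd.DataFrame           # rows = specimens, columns = groups
    unknown_predicted: list[str] = field(default_factory=list)
    unknown_posterior: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# curves and the template

def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12
    if not keep.all():
        warnings.warn("duplicate consecutive points removed before spline "
                      "interpolation", stacklevel=3)
    return points[keep]


def resample_curve(polyline, n_out: int, closed: bool = False,
                   dense: int = 4000) -> np.ndarray:
    """Resample an ordered 3D polyline to ``n_out`` points at equal
    arc-length spacing along an interpolating cubic spline.

    Open curves include both endpoints; closed curves start at the first
    input point (phase 0) and omit the duplicate endpoint.
    """
    pts = _dedupe(np.asarray(polyline, float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("polyline must be (m, 3)")
    if len(pts) < 4:
        raise ValidationError("need >= 4 distinct points to fit a cubic spline")
    if n_out < 2:
        raise ValidationError("n_out must be >= 2")

    if closed:
        if np.linalg.norm(pts[0] - pts[-1]) > 1e-12:
            pts = np.vstack([pts, pts[0]])
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    bc = "periodic" if closed else "natural"
    spline = CubicSpline(chord, pts, bc_type=bc, axis=0)

    t_dense = np.linspace(0.0, chord[-1], max(dense, 10 * len(pts)))
    p_dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if closed:
        targets = np.arange(n_out) * total / n_out
    else:
        targets = np.linspace(0.0, total, n_out)
    t_eq = np.interp(targets, arc, t_dense)
    return spline(t_eq)


def build_template(horns: np.ndarray, ridge_path, cervix_path,
                   label: str = "", group: str | None = None,
                   mirror: bool = False) -> LandmarkConfig:
    """Assemble the 94-point EDJ configuration from the 4 dentine-horn
    landmarks, the marginal-ridge path and the cervix path.

    ``horns`` must be ordered protoconid, metaconid, entoconid, hypoconid
    and the ridge path must pass them in that cyclic order (the lingual
    direction from the protoconid); a violation raises an error naming the
    offending cusp.  ``mirror=True`` reflects right-side teeth into the
    left-side convention (x -> -x) and records the chirality.
    """
    horns = np.asarray(horns, float)
    if horns.shape != (4, 3):
        raise ValidationError("need exactly 4 horn landmarks (4, 3)")
    ridge = np.asarray(ridge_path, float)
    cervix = np.asarray(cervix_path, float)
    if mirror:
        flip = np.array([-1.0, 1.0, 1.0])
        horns = horns * flip
        ridge = ridge * flip
        cervix = cervix * flip

    dense = resample_curve(ridge, 2000, closed=True)
    idx = [int(np.argmin(np.linalg.norm(dense - h, axis=1))) for h in horns]
    # cyclic order check in the path direction, protoconid first
    rel = [(i - idx[0]) % len(dense) for i in idx]
    for c in range(1, 4):
        if rel[c] <= rel[c - 1]:
            raise ValidationError(
                f"ridge path does not pass the {HORN_ORDER[c]} after the "
                f"{HORN_ORDER[c - 1]}: horn ordering inconsistent with the "
                "path direction")

    rolled = np.roll(dense, -idx[0], axis=0)
    cuts = [0] + [rel[1], rel[2], rel[3]] + [len(dense)]
    ridge_semis = []
    for s in range(4):
        seg = rolled[cuts[s]:cuts[s + 1] + 1] if cuts[s + 1] < len(dense) \
            else np.vstack([rolled[cuts[s]:], rolled[:1]])
        # endpoints are the horns; keep interior semilandmarks only
        seg = np.vstack([horns[s], seg[1:-1], horns[(s + 1) % 4]])
        res = resample_curve(seg, RIDGE_SEGMENT_COUNTS[s] + 2, closed=False)
        ridge_semis.append(res[1:-1])

    cervix_pts = resample_curve(cervix, N_CERVIX, closed=True)
    coords = np.vstack([horns] + ridge_semis + [cervix_pts])
    return LandmarkConfig(coords=coords, label=label, group=group,
                          mirrored=mirror)


# ---------------------------------------------------------------------------
# Procrustes

def _as_array(configs) -> tuple[np.ndarray, list[str], list[str | None]]:
    if isinstance(configs, np.ndarray):
        return configs.astype(float), [""] * len(configs), [None] * len(configs)
    coords = np.stack([c.coords for c in configs])
    return coords, [c.label for c in configs], [c.group for c in configs]


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimising ||a @ R - b||."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    return u @ s @ vt


def gpa(configs, tol: float = 1e-8, max_iter: int = 200) -> ShapeSpace:
    """Generalised Procrustes alignment.

    Removes translation and scale (unit centroid size), rotates every
    configuration onto the iteratively re-estimated mean shape until the
    mean changes by less than ``tol``.
    """
    coords, labels, groups = _as_array(configs)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValidationError("need >= 2 configurations")
    if coords.shape[0] >= 2 and len({c.shape for c in coords}) > 1:
        raise ValidationError("configurations must share the landmark count")

    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred ** 2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise ValidationError("degenerate configuration with zero size")
    scaled = centred / sizes[:, None, None]
    for x in scaled:
        if np.linalg.matrix_rank(x, tol=1e-10) < 2:
            raise ValidationError("degenerate (collinear) configuration")

    mean = scaled[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([x @ _optimal_rotation(x, mean) for x in scaled])
        new_mean = aligned.mean(axis=0)
        new_mean /= np.sqrt((new_mean ** 2).sum())
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = np.stack([x @ _optimal_rotation(x, mean) for x in scaled])
    return ShapeSpace(aligned=aligned, centroid_sizes=sizes, mean_shape=mean,
                      labels=labels, groups=groups)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Ordinary (pairwise) Procrustes distance between two configurations:
    Euclidean distance after centring, unit-size scaling and optimal
    rotation of ``a`` onto ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac /= np.sqrt((ac ** 2).sum())
    bc /= np.sqrt((bc ** 2).sum())
    r = _optimal_rotation(ac, bc)
    return float(np.sqrt(((ac @ r - bc) ** 2).sum()))


# ---------------------------------------------------------------------------
# ordinations

def pca(space: ShapeSpace) -> OrdinationResult:
    """Tangent-space principal component analysis of the aligned sample."""
    if space.n < 3:
        raise ValidationError("PCA needs >= 3 specimens")
    x = space.tangent_coords()
    center = np.zeros(x.shape[1])
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    nz = s > 1e-12 * (s[0] if s.size else 1.0)
    scores = u[:, nz] * s[nz]
    var = s[nz] ** 2
    return OrdinationResult(scores=scores, axes=vt[nz], explained=var / var.sum(),
                            kind="pca", center=center, groups=space.groups)


def select_pcs(result: OrdinationResult, target: float = 0.90) -> int:
    """Smallest k whose cumulative explained variance reaches ``target``
    (at least 1)."""
    cum = np.cumsum(result.explained)
    k = int(np.searchsorted(cum, min(target, cum[-1]) - 1e-12) + 1)
    return max(k, 1)


def _group_stats(x: np.ndarray, groups) -> tuple[list[str], dict[str, np.ndarray]]:
    names = []
    members: dict[str, np.ndarray] = {}
    g = np.asarray(groups)
    for name in pd.unique(g):
        if name is None:
            raise ValidationError("every specimen needs a group label")
        members[str(name)] = np.flatnonzero(g == name)
        names.append(str(name))
    return names, members


def bgpca(x: np.ndarray, groups, unknowns: np.ndarray | None = None
          ) -> OrdinationResult:
    """Between-group PCA: PCA of the equally weighted group means; every
    specimen (and any unknowns) is projected onto those axes a posteriori."""
    x = np.asarray(x, float)
    names, members = _group_stats(x, groups)
    if len(names) < 2:
        raise ValidationError("between-group PCA needs >= 2 groups")
    for name in names:
        if members[name].size < 2:
            raise ValidationError(f"group {name!r} has n < 2")
    means = np.stack([x[members[n]].mean(axis=0) for n in names])
    grand = means.mean(axis=0)
    u, s, vt = np.linalg.svd(means - grand, full_matrices=False)
    nz = s > 1e-12 * (s[0] if s.size else 1.0)
    axes = vt[nz]
    var = s[nz] ** 2
    res = OrdinationResult(scores=(x - grand) @ axes.T, axes=axes,
                           explained=var / var.sum(), kind="bgpca",
                           center=grand, groups=list(groups))
    res.group_mean_scores = {n: (means[i] - grand) @ axes.T
                             for i, n in enumerate(names)}
    if unknowns is not None:
        res.unknown_scores = res.project(unknowns)
    res.classification = _classify_nearest(res, names, members, whitened=False)
    return res


def cva(x: np.ndarray, groups, unknowns: np.ndarray | None = None
        ) -> OrdinationResult:
    """Canonical variate analysis on a reduced basis (typically PC scores).

    Axes maximise the between/within variance ratio and are scaled so the
    pooled within-group covariance is the identity in canonical space;
    specimens and unknowns are classified by the smallest Mahalanobis
    distance to the group means (equal priors).
    """
    x = np.asarray(x, float)
    n, k = x.shape
    names, members = _group_stats(x, groups)
    g = len(names)
    if g < 2:
        raise ValidationError("CVA needs >= 2 groups")
    for name in names:
        if members[name].size < 2:
            raise ValidationError(f"group {name!r} has n < 2")
    if k >= n - g:
        raise ValidationError(
            f"CVA needs fewer variables than n - g ({n - g}); reduce the "
            "number of principal components")

    means = np.stack([x[members[nm]].mean(axis=0) for nm in names])
    grand = x.mean(axis=0)
    w = np.zeros((k, k))
    for nm in names:
        d = x[members[nm]] - x[members[nm]].mean(axis=0)
        w += d.T @ d
    w /= (n - g)
    counts = np.array([members[nm].size for nm in names], float)
    b = (counts[:, None] * (means - grand)).T @ (means - grand) / (g - 1)
    try:
        evals, evecs = sla.eigh(b, w)
    except sla.LinAlgError as exc:
        raise ValidationError("singular pooled within-group covariance; "
                              "use fewer principal components") from exc
    order = np.argsort(evals)[::-1][: g - 1]
    axes = evecs[:, order].T          # rows satisfy a W a' = I
    var = np.clip(evals[order], 0.0, None)
    res = OrdinationResult(scores=(x - grand) @ axes.T, axes=axes,
                           explained=var / var.sum() if var.sum() > 0 else var,
                           kind="cva", center=grand, groups=list(groups))
    res.group_mean_scores = {nm: (means[i] - grand) @ axes.T
                             for i, nm in enumerate(names)}
    if unknowns is not None:
        res.unknown_scores = res.project(unknowns)
    res.classification = _classify_nearest(res, names, members, whitened=True)
    return res


def _classify_nearest(res: OrdinationResult, names, members,
                      whitened: bool) -> Classification:
    """Nearest-group-mean classification in ordination space; in whitened
    (canonical) space Euclidean distance is the Mahalanobis distance."""
    mean_scores = np.stack([res.group_mean_scores[n] for n in names])

    def classify(scores):
        d2 = ((scores[:, None, :] - mean_scores[None]) ** 2).sum(axis=2)
        log_post = -0.5 * d2
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        pred = [names[i] for i in np.argmin(d2, axis=1)]
        return pred, pd.DataFrame(post, columns=names)

    pred, post = classify(res.scores)
    out = Classification(predicted=pred, posterior=post)
    if res.unknown_scores is not None:
        upred, upost = classify(np.atleast_2d(res.unknown_scores))
        out.unknown_predicted = upred
        out.unknown_posterior = upost
    return out


def cross_validate(method: str, x: np.ndarray, groups,
                   pc_target: float = 0.90) -> dict:
    """Leave-one-out cross-validated classification.

    For each specimen the ordination (and, for CVA, the PC reduction) is
    refitted without it; the held-out specimen is projected and classified.
    Returns the confusion matrix and per-group/overall correct rates.
    """
    if method not in ("cva", "bgpca"):
        raise ValidationError("method must be 'cva' or 'bgpca'")
    x = np.asarray(x, float)
    g = np.asarray([str(v) for v in groups])
    names = list(pd.unique(g))
    for nm in names:
        if (g == nm).sum() < 3:
            raise ValidationError(f"group {nm!r} has n < 3")
    predicted = []
    for i in range(len(x)):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        xtr, gtr = x[mask], g[mask]
        if method == "cva":
            center = xtr.mean(axis=0)
            u, s, vt = np.linalg.svd(xtr - center, full_matrices=False)
            nz = s > 1e-12 * (s[0] if s.size else 1.0)
            var = s[nz] ** 2
            cum = np.cumsum(var) / var.sum()
            k = int(np.searchsorted(cum, pc_target - 1e-12) + 1)
            k = min(max(k, 1), len(xtr) - len(names) - 1)
            basis = vt[:k]
            res = cva((xtr - center) @ basis.T, gtr,
                      unknowns=(x[i] - center) @ basis.T)
        else:
            res = bgpca(xtr, gtr, unknowns=x[i])
        predicted.append(res.classification.unknown_predicted[0])
    predicted = np.asarray(predicted)
    confusion = pd.crosstab(pd.Series(g, name="true"),
                            pd.Series(predicted, name="predicted"),
                            dropna=False).reindex(index=names,
                                                  columns=names,
                                                  fill_value=0)
    per_group = {nm: float((predicted[g == nm] == nm).mean()) for nm in names}
    return {"confusion": confusion, "per_group_rate": per_group,
            "overall_rate": float((predicted == g).mean()), "method": method}


def allometry_regression(scores: np.ndarray, centroid_sizes,
                         n_perm: int = 10_000, seed: int | None = None
                         ) -> pd.DataFrame:
    """Per-axis regression of ordination score on centroid size.

    Returns slope, the classical F-test p-value and (when n_perm > 0) a
    permutation p-value obtained by shuffling the sizes.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] == 1:
        scores = scores.T
    sizes = np.asarray(centroid_sizes, float)
    n = sizes.size
    if n < 4:
        raise ValidationError("allometry regression needs n >= 4")
    if np.ptp(sizes) <= 0:
        raise ValidationError("centroid sizes are constant")

    sc = sizes - sizes.mean()
    ss = float(sc @ sc)
    rows = []
    rng = np.random.default_rng(seed)
    perms = None
    if n_perm > 0:
        perms = np.stack([rng.permutation(sc) for _ in range(n_perm)])
    for j in range(scores.shape[1]):
        y = scores[:, j]
        yc = y - y.mean()
        slope = float(sc @ yc / ss)
        res = stats.linregress(sizes, y)
        p_f = float(res.pvalue)
        p_perm = np.nan
        if perms is not None:
            null = np.abs(perms @ yc / ss)
            p_perm = float((1 + np.sum(null >= abs(slope))) / (n_perm + 1))
        rows.append({"axis": j + 1, "slope": slope, "p_f": p_f,
                     "p_perm": p_perm})
    return pd.DataFrame(rows).set_index("axis")


# ---------------------------------------------------------------------------
# I/O

def read_tps(path, n_points: int | None = None) -> list[LandmarkConfig]:
    """Read 3D landmark configurations from a TPS-style file (LM3 blocks
    with optional ID= and GROUP= lines)."""
    configs = []
    coords: list[list[float]] = []
    expect = 0
    label = ""
    group: str | None = None

    def flush():
        nonlocal coords, label, group
        if coords:
            if len(coords) != expect:
                raise ValidationError(
                    f"TPS block {label!r}: expected {expect} points, "
                    f"got {len(coords)}")
            configs.append(LandmarkConfig(
                coords=np.array(coords), label=label, group=group,
                n_points=n_points or len(coords)))
        coords, label, group = [], "", None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush()
                expect = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                label = line.split("=", 1)[1]
            elif upper.startswith("GROUP="):
                group = line.split("=", 1)[1]
            else:
                coords.append([float(v) for v in line.split()])
    flush()
    return configs


def write_tps(configs, path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={len(c.coords)}\n")
            for p in c.coords:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write(f"ID={c.label}\n")
            if c.group is not None:
                fh.write(f"GROUP={c.group}\n")


def read_landmarks_csv(path) -> list[LandmarkConfig]:
    """Long-format CSV: specimen, index, x, y, z and optional group/role."""
    df = pd.read_csv(path)
    required = ["specimen", "index", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    configs = []
    for name, sub in df.groupby("specimen", sort=False):
        sub = sub.sort_values("index")
        group = None
        if "group" in sub.columns and sub["group"].notna().any():
            group = str(sub["group"].iloc[0])
        configs.append(LandmarkConfig(
            coords=sub[["x", "y", "z"]].to_numpy(float), label=str(name),
            group=group, n_points=len(sub)))
    return configs
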