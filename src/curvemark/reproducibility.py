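"""Registration and hierarchical variance-components analysis of landmark data.

A landmarking reproducibility study records the same set of facial landmarks
many times: several observers annotate several subjects, each subject imaged
on more than one day, with repeat image captures within a day and repeat
annotations of each image.  After registering all configurations by
Generalised Procrustes Analysis (GPA), each landmark coordinate v is
described by a Gaussian nested random-effects model

    v_ijklm = mu + o_i + s_j + d_jk + c_jkl + r_jklm

with observer (o), subject (s), day-within-subject (d), capture-within-day
(c) and repeat-annotation (r) effects, each with its own standard deviation.
The observer effect is crossed with the subject/day/capture nesting; day and
capture effects are properties of the imaged face and so are shared by all
observers of the same image, while the repeat effect is each observer's own
re-annotation error and is unique to a record.  The model is fitted by
maximum likelihood, separately per landmark, dimension and definition group.

Because repeat annotations of the *same* image share that image's coordinate
frame, GPA is applied to the averages of the repeat pairs at the lowest level
of the hierarchy and each pair's similarity transform is then applied to both
members, so that within-pair differences are preserved up to the pair's
common scale.

For balanced full-factorial designs the model covariance lies in the algebra
generated by Kronecker products of identity and all-ones matrices, so it is
diagonalised exactly by mean/contrast tensor projections; the log-likelihood
is then a closed-form sum over a handful of strata and each evaluation costs
O(n).  Unbalanced data fall back to a dense multivariate-normal likelihood.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .io import LandmarkConfiguration

__all__ = [
    "SimilarityTransform",
    "HierarchicalRecord",
    "HierarchicalDataset",
    "VarianceComponents",
    "ReproducibilitySummary",
    "StructureError",
    "gpa",
    "register_hierarchical",
    "orient_to_convention",
    "fit_components",
    "summarize",
    "combined_sd",
    "LEVELS",
]

LEVELS = ("observer", "subject", "day", "capture", "repeat")

_VAR_FLOOR = 1e-10  # lower bound for variances during optimisation


class StructureError(ValueError):
    """The dataset violates the expected hierarchical structure."""


class NamingError(KeyError):
    """A required landmark name is absent."""


@dataclass
class SimilarityTransform:
    """Similarity map p -> scale * (p - translation) @ rotation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, float) - self.translation) @ self.rotation


@dataclass(frozen=True)
class HierarchicalRecord:
    """One landmark annotation: who, of whom, when, which image, which repeat."""

    observer: str
    subject: str
    day: str
    capture: str
    repeat: str
    group: str
    config: LandmarkConfiguration = field(compare=False)

    @property
    def key(self) -> tuple:
        return (self.group, self.observer, self.subject, self.day,
                self.capture, self.repeat)


@dataclass
class HierarchicalDataset:
    """Collection of hierarchical landmarking records."""

    records: list[HierarchicalRecord]
    registered: bool = False

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (group, observer, subject, day, "
                                 "capture, repeat) index tuples")

    def __len__(self) -> int:
        return len(self.records)

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.records})

    def subset_group(self, group: str) -> "HierarchicalDataset":
        recs = [r for r in self.records if r.group == group]
        return HierarchicalDataset(recs, registered=self.registered)

    def common_landmarks(self) -> list[str]:
        """Landmark names present in every record (order of the first)."""
        sets = [set(r.config.names) for r in self.records]
        common = set.intersection(*sets) if sets else set()
        first = self.records[0].config.names
        dropped = set(first) - common
        if dropped:
            warnings.warn(f"landmarks not shared by all records dropped: "
                          f"{sorted(dropped)}")
        return [n for n in first if n in common]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per record/landmark with x, y, z."""
        names = self.common_landmarks()
        rows = []
        for r in self.records:
            for n in names:
                p = r.config[n]
                rows.append((r.group, r.observer, r.subject, r.day, r.capture,
                             r.repeat, n, p[0], p[1], p[2]))
        return pd.DataFrame(rows, columns=["group", "observer", "subject",
                                           "day", "capture", "repeat",
                                           "landmark", "x", "y", "z"])


@dataclass
class VarianceComponents:
    """ML estimates for one landmark coordinate: mu and the five level SDs."""

    landmark: str
    dimension: int
    mu: float
    sds: dict[str, float]             # level -> SD (mm)
    loglik: float
    boundary: dict[str, bool]         # level -> estimate at the zero boundary
    converged: bool = True

    def __post_init__(self) -> None:
        if set(self.sds) != set(LEVELS):
            raise ValueError(f"sds must have keys {LEVELS}")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("standard deviations must be non-negative")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")


@dataclass
class ReproducibilitySummary:
    """Per-level SDs averaged over landmarks and dimensions, plus combined SD.

    ``combined`` excludes the subject level: it is the reproducibility of a
    single landmark identification on one individual,
    sqrt(sum over dimensions of (sd_o^2 + sd_d^2 + sd_c^2 + sd_r^2)).
    ``sphere_radii`` gives the same combined SD per landmark, the radii of
    the reproducibility spheres used for visualisation.
    """

    level_sds: dict[str, float]
    combined: float
    sphere_radii: dict[str, float]


# ---------------------------------------------------------------------------
# Generalised Procrustes Analysis


def _optimal_rotation(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||X @ R - M||_F (Kabsch)."""
    U, _, Vt = np.linalg.svd(X.T @ M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def gpa(
    configs: Sequence[LandmarkConfiguration],
    with_scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
    objective_history: list | None = None,
) -> tuple[list[LandmarkConfiguration], LandmarkConfiguration,
           list[SimilarityTransform]]:
    """Generalised Procrustes Analysis of landmark configurations.

    Iteratively centres each configuration, scales it to unit centroid size
    (if ``with_scale``), rotates it onto the current mean shape and
    re-estimates the mean, until the mean changes by less than ``tol``.
    Returns the aligned configurations, the Procrustes mean shape, and the
    per-configuration similarity transform that produced each alignment.
    If ``objective_history`` is a list, the sum of squared distances to the
    mean after each iteration is appended to it.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    name_sets = [set(c.names) for c in configs]
    common = set.intersection(*name_sets)
    names = [n for n in configs[0].names if n in common]
    if len(names) < 3:
        raise StructureError(f"only {len(names)} common landmarks; need >= 3")
    X = np.stack([c.subset(names).points for c in configs])
    centroids = X.mean(axis=1, keepdims=True)
    Xc = X - centroids
    sizes = np.linalg.norm(Xc, axis=(1, 2))
    if np.any(sizes == 0):
        raise StructureError("degenerate configuration with zero centroid size")
    scales = 1.0 / sizes if with_scale else np.ones(len(configs))
    Xs = Xc * scales[:, None, None]
    for i in range(len(configs)):
        if np.linalg.matrix_rank(Xs[i], tol=1e-9) < 2:
            warnings.warn(f"configuration {i} is collinear; rotation is "
                          "ambiguous")

    rotations = np.tile(np.eye(3), (len(configs), 1, 1))
    mean = Xs[0].copy()
    aligned = Xs.copy()
    for _ in range(max_iter):
        for i in range(len(configs)):
            rotations[i] = _optimal_rotation(Xs[i], mean)
            aligned[i] = Xs[i] @ rotations[i]
        new_mean = aligned.mean(axis=0)
        if with_scale:
            new_mean = new_mean / np.linalg.norm(new_mean)
        if objective_history is not None:
            objective_history.append(
                float(np.sum((aligned - new_mean) ** 2)))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean

    aligned_configs = [LandmarkConfiguration(list(names), aligned[i])
                       for i in range(len(configs))]
    mean_config = LandmarkConfiguration(list(names), mean)
    transforms = [
        SimilarityTransform(rotation=rotations[i], scale=float(scales[i]),
                            translation=centroids[i, 0])
        for i in range(len(configs))
    ]
    return aligned_configs, mean_config, transforms


def gpa_objective(aligned: Sequence[LandmarkConfiguration],
                  mean: LandmarkConfiguration) -> float:
    """Sum of squared distances of aligned configurations to the mean shape."""
    return float(sum(np.sum((c.points - mean.points) ** 2) for c in aligned))


def register_hierarchical(
    data: HierarchicalDataset, with_scale: bool = True
) -> HierarchicalDataset:
    """Register a hierarchical dataset by GPA on repeat-pair averages.

    Repeat annotations of the same image live in the same image frame, so the
    two repeats of each (group, observer, subject, day, capture) cell are
    averaged, GPA is run on the averages, and each pair's similarity
    transform is applied to both of its members.

    GPA scales each pair average to unit centroid size; the registered
    coordinates are then restored to the mean centroid size of the raw pair
    averages, so that fitted standard deviations keep their mm meaning.
    """
    cells: dict[tuple, list[HierarchicalRecord]] = {}
    for r in data.records:
        cells.setdefault(
            (r.group, r.observer, r.subject, r.day, r.capture), []
        ).append(r)
    for cell, recs in cells.items():
        if len(recs) != 2:
            raise StructureError(
                f"repeats must come in complete pairs; cell {cell} has "
                f"{len(recs)} record(s)"
            )
    names = data.common_landmarks()
    cell_keys = sorted(cells)
    averages = []
    for cell in cell_keys:
        pts = np.mean([r.config.subset(names).points for r in cells[cell]],
                      axis=0)
        averages.append(LandmarkConfiguration(list(names), pts))
    _, _, transforms = gpa(averages, with_scale=with_scale)
    mean_size = float(np.mean([1.0 / tf.scale for tf in transforms])) \
        if with_scale else 1.0
    new_records = []
    for cell, tf in zip(cell_keys, transforms):
        for r in cells[cell]:
            pts = mean_size * tf.apply(r.config.subset(names).points)
            new_records.append(
                HierarchicalRecord(
                    observer=r.observer, subject=r.subject, day=r.day,
                    capture=r.capture, repeat=r.repeat, group=r.group,
                    config=LandmarkConfiguration(list(names), pts),
                )
            )
    return HierarchicalDataset(new_records, registered=True)


def orient_to_convention(
    data: HierarchicalDataset,
    exocanthion_right: str = "exocanthion right",
    exocanthion_left: str = "exocanthion left",
    nasion: str = "nasion",
    subnasale: str = "subnasale",
) -> HierarchicalDataset:
    """Rotate all configurations into the anatomical display convention.

    The mean exocanthion-to-exocanthion vector becomes +x (left-right), the
    mean subnasale-to-nasion vector lies in the x-y plane with positive y
    (bottom-top), and z completes a right-handed frame (back-front).
    """
    names = data.common_landmarks()
    for required in (exocanthion_right, exocanthion_left, nasion, subnasale):
        if required not in names:
            raise NamingError(f"landmark {required!r} required for "
                              "orientation is absent")
    mean = np.mean([r.config.subset(names).points for r in data.records],
                   axis=0)
    def at(nm):
        return mean[names.index(nm)]
    xhat = at(exocanthion_right) - at(exocanthion_left)
    xhat = xhat / np.linalg.norm(xhat)
    v = at(nasion) - at(subnasale)
    yhat = v - (v @ xhat) * xhat
    yhat = yhat / np.linalg.norm(yhat)
    zhat = np.cross(xhat, yhat)
    R = np.column_stack([xhat, yhat, zhat])  # new coords = points @ R
    new_records = [
        HierarchicalRecord(
            observer=r.observer, subject=r.subject, day=r.day,
            capture=r.capture, repeat=r.repeat, group=r.group,
            config=LandmarkConfiguration(list(names),
                                         r.config.subset(names).points @ R),
        )
        for r in data.records
    ]
    return HierarchicalDataset(new_records, registered=data.registered)


# ---------------------------------------------------------------------------
# variance-components ML


def _extract_design(
    data: HierarchicalDataset, landmark: str, dimension: int,
    group: str | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, int]]:
    records = data.records
    if group is not None:
        records = [r for r in records if r.group == group]
    if not records:
        raise StructureError(f"no records for group {group!r}")
    groups_present = {r.group for r in records}
    if len(groups_present) > 1:
        raise StructureError(
            f"records span groups {sorted(groups_present)}; fit one "
            "definition group at a time (pass group=...)"
        )
    v = np.empty(len(records))
    labels = {
        "observer": [], "subject": [], "day": [], "capture": [], "repeat": [],
    }
    for i, r in enumerate(records):
        if landmark not in r.config:
            raise NamingError(f"landmark {landmark!r} missing from a record")
        v[i] = r.config[landmark][dimension]
        labels["observer"].append(r.observer)
        labels["subject"].append(r.subject)
        # nested labels: a day/capture/repeat is identified jointly with
        # its parents
        labels["day"].append((r.subject, r.day))
        labels["capture"].append((r.subject, r.day, r.capture))
        labels["repeat"].append((r.subject, r.day, r.capture, r.repeat))
    codes = {}
    counts = {}
    for lev, lab in labels.items():
        c, uniq = pd.factorize(pd.Series(lab).astype(str), sort=True)
        codes[lev] = c
        counts[lev] = len(uniq)
    return v, codes, counts


def _balanced_layout(
    v: np.ndarray, codes: Mapping[str, np.ndarray], counts: Mapping[str, int]
) -> np.ndarray | None:
    """Reshape v to an (o, s, d, c, m) array if the design is balanced."""
    n_o = counts["observer"]
    n_s = counts["subject"]
    if counts["day"] % n_s or counts["capture"] % counts["day"] \
            or counts["repeat"] % counts["capture"]:
        return None
    n_d = counts["day"] // n_s
    n_c = counts["capture"] // counts["day"]
    n_m = counts["repeat"] // counts["capture"]
    shape = (n_o, n_s, n_d, n_c, n_m)
    if len(v) != int(np.prod(shape)):
        return None
    # within-parent positions for the nested factors
    d_pos = codes["day"] % n_d
    c_pos = codes["capture"] % n_c
    m_pos = codes["repeat"] % n_m
    # check the nested codes are consistent blocks
    if not (np.array_equal(codes["day"] // n_d, codes["subject"])
            and np.array_equal(codes["capture"] // n_c, codes["day"])
            and np.array_equal(codes["repeat"] // n_m, codes["capture"])):
        return None
    arr = np.full(shape, np.nan)
    arr[codes["observer"], codes["subject"], d_pos, c_pos, m_pos] = v
    if np.any(np.isnan(arr)):
        return None
    return arr


def _balanced_strata(arr: np.ndarray) -> list[tuple[np.ndarray, float, float]]:
    """Spectral strata of the balanced design.

    Returns (coef, multiplicity, sum-of-squares) per mean/contrast pattern,
    where ``coef`` holds the multiplier of each variance
    (observer, subject, day, capture, repeat) in that stratum's eigenvalue.
    The all-mean stratum carries the profiled grand mean: SS = 0,
    multiplicity 1 (its log-determinant term still enters the ML likelihood).
    """
    n_o, n_s, n_d, n_c, n_m = arr.shape
    centered = arr - arr.mean()
    strata = []
    for pattern in itertools.product((1, 0), repeat=5):
        a_o, a_s, a_d, a_c, a_m = pattern
        X = centered
        mult = 1.0
        for ax, (is_mean, nf) in enumerate(zip(pattern, arr.shape)):
            if is_mean:
                X = np.broadcast_to(X.mean(axis=ax, keepdims=True), arr.shape)
            else:
                X = X - X.mean(axis=ax, keepdims=True)
                mult *= nf - 1
        if mult == 0:
            continue
        ss = float(np.sum(X * X))
        if all(pattern):
            ss = 0.0  # grand-mean stratum: mu profiled out
        coef = np.array([
            n_s * n_d * n_c * n_m if (a_s and a_d and a_c and a_m) else 0.0,
            n_o * n_d * n_c * n_m if (a_o and a_d and a_c and a_m) else 0.0,
            n_o * n_c * n_m if (a_o and a_c and a_m) else 0.0,
            n_o * n_m if (a_o and a_m) else 0.0,
            1.0,
        ])
        strata.append((coef, mult, ss))
    return strata


def _nll_balanced(log_var: np.ndarray, strata, n: int, reml_drop_mean: bool
                  ) -> float:
    var = np.exp(log_var)
    nll = 0.5 * n * np.log(2 * np.pi)
    for coef, mult, ss in strata:
        lam = float(coef @ var)
        if reml_drop_mean and ss == 0.0 and mult == 1.0:
            continue
        nll += 0.5 * (mult * np.log(lam) + ss / lam)
    return nll


def _dense_nll(log_var: np.ndarray, v: np.ndarray,
               Zs: list[np.ndarray]) -> float:
    var = np.exp(log_var)
    n = len(v)
    V = var[-1] * np.eye(n)
    for s2, Z in zip(var[:-1], Zs):
        V += s2 * (Z @ Z.T)
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = float(v @ Vi1 / (ones @ Vi1))
    resid = v - mu
    quad = float(resid @ linalg.cho_solve(cf, resid))
    return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _moment_start(strata, n_counts) -> np.ndarray:
    """Henderson-style sequential method-of-moments starting variances."""
    by_pattern = {tuple(coef): (mult, ss) for coef, mult, ss in strata}

    def ms(coef_key):
        entry = by_pattern.get(coef_key)
        if entry is None or entry[0] == 0:
            return None
        mult, ss = entry
        return ss / mult

    n_o, n_s, n_d, n_c, n_m = n_counts
    est = np.full(5, np.nan)
    # repeat: all-contrast stratum has eigenvalue sigma_r^2 exactly
    base = None
    for coef, mult, ss in strata:
        if np.array_equal(coef, [0, 0, 0, 0, 1]) and mult > 0:
            base = ss / mult
    est[4] = base if base is not None else 1.0
    for coef, mult, ss in strata:
        lam = ss / mult if mult else None
        if lam is None:
            continue
        # solve each stratum for the highest-order component it contains
        resid = lam - est[4]
        if coef[0] > 0 and coef[1] == 0:
            est[0] = resid / coef[0]
        elif coef[3] > 0 and coef[2] == 0 and coef[1] == 0 and coef[0] == 0:
            est[3] = resid / coef[3]
    # fill the rest by subtracting known lower-order contributions
    for coef, mult, ss in strata:
        if mult == 0:
            continue
        lam = ss / mult
        for j in (2, 1):
            if coef[j] > 0 and all(coef[k] == 0 or not np.isnan(est[k])
                                   for k in range(5) if k != j):
                known = sum(coef[k] * est[k] for k in range(5)
                            if k != j and coef[k] > 0 and not np.isnan(est[k]))
                if np.isnan(est[j]):
                    est[j] = (lam - known) / coef[j]
    est = np.where(np.isnan(est), est[4], est)
    return np.clip(est, _VAR_FLOOR * 10, None)


def fit_components(
    data: HierarchicalDataset,
    landmark: str,
    dimension: int,
    *,
    group: str | None = None,
    reml: bool = False,
    n_starts: int = 4,
) -> VarianceComponents:
    """Fit the nested random-effects model for one landmark coordinate by ML.

    Optimises the Gaussian likelihood over log-variances (non-negativity by
    construction) from a method-of-moments start plus scaled perturbations.
    Levels with a single populated stratum are inestimable and fixed at 0
    with a boundary flag; estimated variances that converge to the floor are
    likewise reported as 0 and flagged.
    """
    if not data.registered:
        warnings.warn("fitting an unregistered dataset; run "
                      "register_hierarchical first for real studies")
    v, codes, counts = _extract_design(data, landmark, dimension, group)
    n = len(v)
    arr = _balanced_layout(v, codes, counts)
    fixed_zero = np.zeros(5, dtype=bool)
    if arr is not None:
        shape = arr.shape
        # levels with a single unit provide no contrast: inestimable
        fixed_zero = np.array([s <= 1 for s in shape])
        strata = _balanced_strata(arr)
        n_counts = shape
        start = _moment_start(strata, shape)

        def nll(log_var):
            lv = log_var.copy()
            lv[fixed_zero] = np.log(_VAR_FLOOR)
            return _nll_balanced(lv, strata, n, reml)
    else:
        if n > 4000:
            raise StructureError(
                "unbalanced design too large for the dense likelihood path"
            )
        Zs = []
        for lev in LEVELS[:-1]:
            c = codes[lev]
            k = counts[lev]
            if k <= 1:
                fixed_zero[LEVELS.index(lev)] = True
            Z = np.zeros((n, k))
            Z[np.arange(n), c] = 1.0
            Zs.append(Z)
        start = np.full(5, max(np.var(v), 1e-6) / 5)

        def nll(log_var):
            lv = log_var.copy()
            lv[fixed_zero] = np.log(_VAR_FLOOR)
            return _dense_nll(lv, v, Zs)

    rng = np.random.default_rng(0)
    best = None
    starts = [np.log(start)]
    for _ in range(n_starts - 1):
        starts.append(np.log(start) + rng.normal(scale=1.0, size=5))
    bounds = [(np.log(_VAR_FLOOR), 20.0)] * 5
    for x0 in starts:
        x0 = np.clip(x0, np.log(_VAR_FLOOR), 20.0)
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-components optimisation failed to "
                           "converge from all starts")
    var = np.exp(best.x)
    var[fixed_zero] = 0.0
    boundary = {}
    sds = {}
    for i, lev in enumerate(LEVELS):
        at_floor = var[i] <= _VAR_FLOOR * 100
        boundary[lev] = bool(at_floor or fixed_zero[i])
        sds[lev] = 0.0 if at_floor else float(np.sqrt(var[i]))
    # profiled grand mean
    mu = float(np.mean(v))
    return VarianceComponents(
        landmark=landmark, dimension=dimension, mu=mu, sds=sds,
        loglik=float(-best.fun), boundary=boundary,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# summaries


def combined_sd(level_sds: Mapping[str, float], n_dims: int = 3) -> float:
    """Combined per-identification SD from per-level SDs shared across dims.

    sqrt(n_dims * (sd_o^2 + sd_d^2 + sd_c^2 + sd_r^2)) -- the subject level
    is excluded because it reflects real anatomical variation, not
    identification error.
    """
    total = sum(level_sds[lev] ** 2 for lev in ("observer", "day", "capture",
                                                "repeat"))
    return float(np.sqrt(n_dims * total))


def summarize(
    components: Iterable[VarianceComponents],
) -> ReproducibilitySummary:
    """Average per-level SDs over landmarks and dimensions; combined SD.

    Averaging is over raw SDs (not variances).  The combined reproducibility
    uses the averaged SDs; per-landmark sphere radii use each landmark's own
    per-dimension variances:
    radius = sqrt(sum over dims of (sd_o^2 + sd_d^2 + sd_c^2 + sd_r^2)).
    """
    comps = list(components)
    if not comps:
        raise ValueError("no components to summarise")
    level_sds = {
        lev: float(np.mean([c.sds[lev] for c in comps])) for lev in LEVELS
    }
    combined = combined_sd(level_sds)
    radii: dict[str, float] = {}
    for lm in sorted({c.landmark for c in comps}):
        total = sum(
            c.sds[lev] ** 2
            for c in comps if c.landmark == lm
            for lev in ("observer", "day", "capture", "repeat")
        )
        radii[lm] = float(np.sqrt(total))
    return ReproducibilitySummary(level_sds=level_sds, combined=combined,
                                  sphere_radii=radii)


def components_frame(components: Iterable[VarianceComponents]) -> pd.DataFrame:
    """Tidy table (landmark, dimension, level, sd, boundary) of fitted SDs."""
    rows = []
    for c in components:
        for lev in LEVELS:
            rows.append((c.landmark, c.dimension, lev, c.sds[lev],
                         c.boundary[lev]))
    return pd.DataFrame(rows, columns=["landmark", "dimension", "level",
                                       "sd", "boundary"])
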