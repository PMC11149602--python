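"""Data-driven tissue basis construction.

A basis element is a nonincreasing nonnegative residue R_k plus an input
delay Delta_k; its tissue curve is the frame-averaged convolution of R_k
with the delayed whole-blood input.  Elements are derived from the study's
own data: voxel time courses are clustered, one constrained residue is
fitted per cluster mean, and the number of elements kept is chosen by
cross-validation over voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .frames import (
    SEC_PER_MIN,
    FitWeights,
    FrameBinner,
    FrameSchedule,
    InputFunction,
)
from .image import DynamicImage
from .residue import Residue

__all__ = [
    "TissueBasisSet",
    "SegmentationResult",
    "segment_tacs",
    "fit_tac_residue",
    "select_basis",
    "default_knots",
    "save_basis",
    "load_basis",
]


def _weighted_nnls(A: np.ndarray, y: np.ndarray, w: np.ndarray):
    """min_{x >= 0} sum_j w_j (y_j - (Ax)_j)^2; returns (x, wrss)."""
    sw = np.sqrt(w)
    x, rnorm = nnls(A * sw[:, None], y * sw)
    return x, float(rnorm**2)


def default_knots(T_end_s: float, n_knots: int = 30) -> np.ndarray:
    """Geometric knot grid on [0, T_end]: dense early, sparse late."""
    return np.concatenate([[0.0], np.geomspace(1.0, T_end_s, n_knots - 1)])


def _ramp_columns(knots: np.ndarray, node_t: np.ndarray) -> np.ndarray:
    """Piecewise-linear 'step down after knot m' functions e_m on the node grid.

    e_m equals 1 up to knot m and 0 from knot m+1 on; any nonincreasing
    nonnegative piecewise-linear residue on the knot grid is a unique
    nonnegative combination sum_m beta_m e_m.
    """
    M = knots.size
    cols = np.empty((node_t.size, M))
    for m in range(M):
        vals = np.zeros(M)
        vals[: m + 1] = 1.0
        cols[:, m] = np.interp(node_t, knots, vals)
    return cols


def _beta_to_values(beta: np.ndarray) -> np.ndarray:
    return np.cumsum(beta[::-1])[::-1]


class _ConvolutionEngine:
    """FFT convolution of residue-shaped columns with a delayed input curve."""

    def __init__(self, schedule: FrameSchedule, aif: InputFunction, fine_dt_s: float):
        self.binner = FrameBinner(schedule, fine_dt_s)
        self.dt = fine_dt_s
        self.aif = aif
        n = self.binner.node_t.size
        self.n = n
        self.nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
        self._cp_fft_cache: dict[float, np.ndarray] = {}

    def cp_fft(self, delay_s: float) -> np.ndarray:
        key = round(float(delay_s), 9)
        if key not in self._cp_fft_cache:
            cp = self.aif(self.binner.node_t - delay_s)
            self._cp_fft_cache[key] = np.fft.rfft(cp, self.nfft)
        return self._cp_fft_cache[key]

    def convolve(self, cols: np.ndarray, delay_s: float) -> np.ndarray:
        """Node-grid curves integral_0^t col(t-s) Cp(s - delay) ds, per column."""
        cols2 = np.atleast_2d(cols.T).T
        cf = np.fft.rfft(cols2, self.nfft, axis=0)
        out = np.fft.irfft(cf * self.cp_fft(delay_s)[:, None], self.nfft, axis=0)
        out = out[: self.n] * (self.dt / SEC_PER_MIN)
        # inputs are nonnegative; clear FFT round-off negatives
        np.clip(out, 0.0, None, out=out)
        return out

    def frame_average(self, node_cols: np.ndarray, shift_s: float = 0.0) -> np.ndarray:
        """Frame means of node-grid curves, optionally right-shifted by shift_s."""
        node_cols = np.atleast_2d(node_cols.T).T
        if shift_s == 0.0:
            mid = 0.5 * (node_cols[:-1] + node_cols[1:])
        else:
            mid = np.empty((self.binner.mid_t.size, node_cols.shape[1]))
            t = self.binner.mid_t - shift_s
            for k in range(node_cols.shape[1]):
                mid[:, k] = np.interp(t, self.binner.node_t, node_cols[:, k], left=0.0)
        sums = np.add.reduceat(mid, self.binner.edges[:-1], axis=0)
        return sums / self.binner.counts[:, None]


@dataclass
class TissueBasisSet:
    """K basis residues with delays and their frame-averaged tissue curves."""

    residues: list[Residue]
    delays_s: np.ndarray
    schedule: FrameSchedule
    aif: InputFunction
    fine_dt_s: float = 1.0

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        if len(self.residues) < 1:
            raise ValueError("basis needs at least one element")
        if self.delays_s.size != len(self.residues):
            raise ValueError("one delay per basis residue required")
        self._engine = _ConvolutionEngine(self.schedule, self.aif, self.fine_dt_s)
        node_t = self._engine.binner.node_t
        cols = np.column_stack([r(node_t) for r in self.residues])
        self._mu_nodes = np.column_stack(
            [
                self._engine.convolve(cols[:, k], self.delays_s[k])[:, 0]
                for k in range(self.K)
            ]
        )
        self._frame_cache: dict[float, np.ndarray] = {}

    @property
    def K(self) -> int:
        return len(self.residues)

    @property
    def mu_node_t(self) -> np.ndarray:
        return self._engine.binner.node_t

    @property
    def mu_nodes(self) -> np.ndarray:
        """Fine-grid tissue curves, shape (n_nodes, K)."""
        return self._mu_nodes

    def frame_matrix(self, delta_s: float = 0.0) -> np.ndarray:
        """(J, K) frame-averaged basis curves mu_k(t_j - delta)."""
        key = round(float(delta_s), 9)
        if key not in self._frame_cache:
            self._frame_cache[key] = self._engine.frame_average(self._mu_nodes, key)
        return self._frame_cache[key]

    def residue_param_table(self, t_star_s: float, ext_convention: str = "retained"):
        """Per-element (V_b, V_d, K_d, K_i); all four are linear in amplitude."""
        from .residue import decompose, kinetic_params

        rows = []
        T_end = self.schedule.total_duration_s
        for r in self.residues:
            p = kinetic_params(decompose(r, t_star_s, T_end), ext_convention)
            rows.append([p.V_b, p.V_d, p.K_d, p.K_i])
        return np.asarray(rows)


@dataclass
class SegmentationResult:
    """Voxel clustering of time courses plus cluster-mean curves."""

    labels: np.ndarray  # (N,) segment index per masked voxel
    mean_tacs: np.ndarray  # (S, J)
    tacs: np.ndarray  # (N, J) the clustered voxel curves
    sizes: np.ndarray  # (S,)

    @property
    def S(self) -> int:
        return self.mean_tacs.shape[0]


def _normalize_tacs(tacs: np.ndarray, durations: np.ndarray) -> np.ndarray:
    integral = tacs @ durations
    safe = np.where(integral > 0, integral, 1.0)
    return tacs / safe[:, None]


def segment_tacs(
    image: DynamicImage,
    S: int,
    seed: int = 0,
    max_cluster_voxels: int = 50_000,
) -> SegmentationResult:
    """Partition masked voxels into S clusters of similar normalized shape.

    Curves are amplitude-normalized (divided by their time integral) before
    k-means clustering, so clusters group kinetic shapes, not magnitudes.
    Deterministic given the seed.
    """
    tacs = image.masked_tacs()
    N = tacs.shape[0]
    if S > N:
        raise ValueError(f"requested {S} segments but only {N} masked voxels")
    if S == 1:
        labels = np.zeros(N, dtype=int)
        return SegmentationResult(labels, tacs.mean(axis=0, keepdims=True), tacs, np.array([N]))
    from sklearn.cluster import KMeans

    X = _normalize_tacs(tacs, image.schedule.duration_s)
    rng = np.random.default_rng(seed)
    if N > max_cluster_voxels:
        idx = rng.choice(N, size=max_cluster_voxels, replace=False)
        km = KMeans(n_clusters=S, n_init=4, random_state=seed).fit(X[idx])
        labels = km.predict(X)
    else:
        km = KMeans(n_clusters=S, n_init=4, random_state=seed).fit(X)
        labels = km.labels_.copy()
    mean_tacs = np.vstack(
        [
            tacs[labels == s].mean(axis=0) if np.any(labels == s) else np.zeros(tacs.shape[1])
            for s in range(S)
        ]
    )
    sizes = np.bincount(labels, minlength=S)
    return SegmentationResult(labels, mean_tacs, tacs, sizes)


class _ResidueDesign:
    """Cached frame-design matrices for constrained residue fitting."""

    def __init__(
        self,
        schedule: FrameSchedule,
        aif: InputFunction,
        knots_s: np.ndarray,
        fine_dt_s: float = 1.0,
    ):
        self.knots = np.asarray(knots_s, dtype=float)
        self.engine = _ConvolutionEngine(schedule, aif, fine_dt_s)
        self._ramps = _ramp_columns(self.knots, self.engine.binner.node_t)
        self._cache: dict[float, np.ndarray] = {}

    def matrix(self, delay_s: float) -> np.ndarray:
        key = round(float(delay_s), 9)
        if key not in self._cache:
            node_curves = self.engine.convolve(self._ramps, delay_s)
            self._cache[key] = self.engine.frame_average(node_curves)
        return self._cache[key]


def fit_tac_residue(
    tac: np.ndarray,
    aif: InputFunction,
    schedule: FrameSchedule,
    weights: FitWeights,
    delay_grid_s: np.ndarray | None = None,
    knots_s: np.ndarray | None = None,
    fine_dt_s: float = 1.0,
    _design: "_ResidueDesign | None" = None,
) -> tuple[Residue, float, float]:
    """Best admissible residue + input delay for one time course.

    The residue is parameterized by nonnegative decrements on a knot grid,
    making the weighted least-squares problem a nonnegative QP solved by
    NNLS; the delay is optimized by grid search.  Returns
    ``(residue, delay_s, wrss)``; an all-zero curve yields the zero residue.
    """
    tac = np.asarray(tac, dtype=float)
    if delay_grid_s is None:
        delay_grid_s = np.arange(-20.0, 60.0 + 1e-9, 2.0)
    if knots_s is None:
        knots_s = default_knots(schedule.total_duration_s)
    if _design is None:
        _design = _ResidueDesign(schedule, aif, knots_s, fine_dt_s)
    if not np.any(tac != 0.0):
        zero = Residue(_design.knots, np.zeros(_design.knots.size))
        return zero, 0.0, 0.0
    best = None
    for delay in np.atleast_1d(delay_grid_s):
        A = _design.matrix(float(delay))
        beta, wrss = _weighted_nnls(A, tac, weights.w)
        if best is None or wrss < best[2]:
            best = (beta, float(delay), wrss)
    beta, delay, wrss = best
    return Residue(_design.knots, _beta_to_values(beta)), delay, wrss


def _voxel_wrss(
    mu: np.ndarray, tacs: np.ndarray, w: np.ndarray, gcv: bool
) -> float:
    """Summed (optionally GCV-adjusted) NNLS misfit of voxel curves on mu."""
    J = tacs.shape[1]
    total = 0.0
    for z in tacs:
        alpha, wrss = _weighted_nnls(mu, z, w)
        if gcv:
            df = min(int(np.count_nonzero(alpha)) + 1, J - 1)
            wrss = wrss / (1.0 - df / J) ** 2
        total += wrss
    return total


def _greedy_order(
    mu_all: np.ndarray, tacs: np.ndarray, w: np.ndarray, k_max: int, priority: np.ndarray
) -> list[int]:
    """Order candidate columns by greedy training-WRSS reduction."""
    chosen: list[int] = []
    remaining = list(np.argsort(-priority))
    while len(chosen) < k_max and remaining:
        scores = []
        for c in remaining:
            mu = mu_all[:, chosen + [c]]
            scores.append(_voxel_wrss(mu, tacs, w, gcv=False))
        best = int(np.argmin(scores))
        chosen.append(remaining.pop(best))
    return chosen


def select_basis(
    segments: SegmentationResult,
    aif: InputFunction,
    schedule: FrameSchedule,
    weights: FitWeights,
    K_grid: list[int] | np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
    delay_grid_s: np.ndarray | None = None,
    knots_s: np.ndarray | None = None,
    voxel_subsample: int = 200,
    fine_dt_s: float = 1.0,
    dedup_cos: float = 0.999,
) -> TissueBasisSet:
    """Cross-validation-guided choice of the basis from segment residue fits.

    Folds split voxels.  Within each fold, segment mean curves and their
    candidate residues are rebuilt from training voxels only, and each
    held-out voxel is predicted by an amplitude-only rescaling of its
    segment's K-basis fit.  (Refitting all K amplitudes per held-out voxel
    would make the score nonincreasing in K: clustering aligns candidate
    shapes with noise directions that a free NNLS then exploits.  The
    amplitude-only prediction lets extra elements help only through real
    shape structure, giving the score a genuine minimum.)  Near-ties —
    within 0.1% relative — break toward smaller K; the final basis refits
    candidates on all voxels.
    """
    K_grid = sorted(int(k) for k in np.atleast_1d(K_grid))
    if not K_grid:
        raise ValueError("empty K_grid")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if knots_s is None:
        knots_s = default_knots(schedule.total_duration_s)
    design = _ResidueDesign(schedule, aif, knots_s, fine_dt_s)
    engine = design.engine
    node_t = engine.binner.node_t

    def candidate_curves(member_tacs_per_segment):
        """Fit one residue per segment mean; return (candidates, mu, priority)."""
        cands, signals = [], []
        for tacs_s in member_tacs_per_segment:
            if tacs_s.shape[0] == 0:
                continue
            tac = tacs_s.mean(axis=0)
            res, delay, _ = fit_tac_residue(
                tac, aif, schedule, weights, delay_grid_s, knots_s, fine_dt_s,
                _design=design,
            )
            if np.any(res.values > 0):
                cands.append((res, delay))
                signals.append(float(tacs_s.shape[0] * (tac @ schedule.duration_s)))
        if not cands:
            raise ValueError("all segment residue fits are degenerate (zero signal)")
        mu = np.column_stack(
            [
                engine.frame_average(engine.convolve(res(node_t), delay))[:, 0]
                for res, delay in cands
            ]
        )
        # prune near-duplicate candidates (segments that split one kinetic
        # shape on noise alone), keeping the highest-signal representative
        w = weights.w
        keep: list[int] = []
        for c in np.argsort(-np.asarray(signals)):
            nc = mu[:, c] / np.sqrt(np.sum(w * mu[:, c] ** 2))
            dup = any(
                np.sum(w * nc * mu[:, k] / np.sqrt(np.sum(w * mu[:, k] ** 2)))
                > dedup_cos
                for k in keep
            )
            if not dup:
                keep.append(int(c))
        keep.sort()
        cands = [cands[c] for c in keep]
        mu = mu[:, keep]
        signals = [signals[c] for c in keep]
        return cands, mu, np.asarray(signals)

    rng = np.random.default_rng(seed)
    N = segments.tacs.shape[0]
    sub = rng.choice(N, size=min(voxel_subsample, N), replace=False)
    tacs = segments.tacs[sub]
    labels = segments.labels[sub]
    n_sub = tacs.shape[0]
    folds = np.resize(np.arange(cv_folds), n_sub)
    rng.shuffle(folds)
    k_cap = max(K_grid)

    w = weights.w
    cv_score = {k: 0.0 for k in K_grid}
    for f in range(cv_folds):
        train_sel = folds != f
        val_idx = np.flatnonzero(~train_sel)
        if not np.any(train_sel) or val_idx.size == 0:
            continue
        train_means = [
            tacs[train_sel & (labels == s)].mean(axis=0)
            if np.any(train_sel & (labels == s))
            else None
            for s in range(segments.S)
        ]
        _, mu_f, prio_f = candidate_curves(
            [tacs[train_sel & (labels == s)] for s in range(segments.S)]
        )
        order = _greedy_order(
            mu_f, tacs[train_sel], w, min(k_cap, mu_f.shape[1]), prio_f
        )
        for k in K_grid:
            cols = order[: min(k, len(order))]
            fitted_shape: dict[int, np.ndarray] = {}
            for s in range(segments.S):
                if train_means[s] is None:
                    continue
                alpha, _ = _weighted_nnls(mu_f[:, cols], train_means[s], w)
                fitted_shape[s] = mu_f[:, cols] @ alpha
            for v in val_idx:
                F = fitted_shape.get(int(labels[v]))
                if F is None:
                    continue
                denom = float(np.sum(w * F * F))
                a = max(0.0, float(np.sum(w * tacs[v] * F)) / denom) if denom > 0 else 0.0
                cv_score[k] += float(np.sum(w * (tacs[v] - a * F) ** 2))
    best_k = K_grid[0]
    for k in K_grid[1:]:
        if cv_score[k] < cv_score[best_k] * (1.0 - 1e-3):
            best_k = k

    candidates, mu_all, priority = candidate_curves(
        [segments.tacs[segments.labels == s] for s in range(segments.S)]
    )
    final_order = _greedy_order(
        mu_all, tacs, weights.w, min(k_cap, mu_all.shape[1]), priority
    )
    chosen = final_order[: min(best_k, len(final_order))]
    residues = [candidates[c][0] for c in chosen]
    delays = np.array([candidates[c][1] for c in chosen])
    return TissueBasisSet(residues, delays, schedule, aif, fine_dt_s)


def save_basis(basis: TissueBasisSet, path) -> None:
    """Persist a basis (residues, delays, schedule, input samples) as JSON."""
    payload = {
        "fine_dt_s": basis.fine_dt_s,
        "delays_s": basis.delays_s.tolist(),
        "residues": [
            {"grid_s": r.grid_s.tolist(), "values": r.values.tolist()}
            for r in basis.residues
        ],
        "schedule": {
            "start_s": basis.schedule.start_s.tolist(),
            "duration_s": basis.schedule.duration_s.tolist(),
            "isotope_halflife_min": basis.schedule.isotope_halflife_min,
        },
        "aif": {
            "sample_times_s": basis.aif.sample_times_s.tolist(),
            "activity": basis.aif.activity.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_basis(path) -> TissueBasisSet:
    with open(path) as fh:
        payload = json.load(fh)
    schedule = FrameSchedule(
        np.asarray(payload["schedule"]["start_s"]),
        np.asarray(payload["schedule"]["duration_s"]),
        payload["schedule"]["isotope_halflife_min"],
    )
    aif = InputFunction(
        np.asarray(payload["aif"]["sample_times_s"]),
        np.asarray(payload["aif"]["activity"]),
    )
    residues = [
        Residue(np.asarray(r["grid_s"]), np.asarray(r["values"]))
        for r in payload["residues"]
    ]
    return TissueBasisSet(
        residues,
        np.asarray(payload["delays_s"]),
        schedule,
        aif,
        payload["fine_dt_s"],
    )
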