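"""Fully connected CRF refinement of per-pixel class probabilities.

Every pixel is a node; every pair interacts through a two-kernel Gaussian
potential.  With unary cost theta_a(x_a) = -log P(x_a) from the network and
Potts compatibility mu(x_a, x_b) = [x_a != x_b], the energy of a labeling is

    E(x) = sum_a theta_a(x_a) + sum_{b < a} mu(x_a, x_b) * k(a, b)

    k(a, b) = w1 * exp(-|p_a - p_b|^2 / (2 sigma_alpha^2)
                       - |I_a - I_b|^2 / (2 sigma_beta^2))
            + w2 * exp(-|p_a - p_b|^2 / (2 sigma_gamma^2))

where p are pixel positions (0-based, pixel units) and I raw RGB colors in
0..255.  The appearance kernel pulls similar-colored nearby pixels toward a
common label; the smoothness kernel removes isolated noise.  Inference uses
mean-field approximation: a factorized Q is iterated toward minimum KL
divergence from the Gibbs distribution, which under Potts compatibility
reduces to the message m_a(l) = sum_{b != a} k(a, b) * (1 - Q_b(l)) and the
update Q_a(l) proportional to exp(-theta_a(l) - m_a(l)).

Pair sums are computed exactly and densely (O(N^2)); a configurable size cap
(default 128 x 128 pixels) guards runtime — tile larger inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dfcn import ProbabilityMap, predict_labels

PROB_EPS = 1e-8  # clamp before the log; the unary is undefined at P = 0
DEFAULT_SIZE_CAP = 128 * 128


class GridTooLargeError(ValueError):
    """Raised when a problem exceeds the dense-sum safety cap."""


@dataclass(frozen=True)
class CRFParams:
    """Kernel weights/bandwidths and the mean-field iteration count.

    Defaults w2 = sigma_gamma = 1 and 10 iterations; w1, sigma_alpha and
    sigma_beta are the quantities worth grid-searching per dataset.
    """

    w1: float = 1.0
    w2: float = 1.0
    sigma_alpha: float = 10.0
    sigma_beta: float = 10.0
    sigma_gamma: float = 1.0
    n_iterations: int = 10

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("kernel weights must be nonnegative")
        if min(self.sigma_alpha, self.sigma_beta, self.sigma_gamma) <= 0:
            raise ValueError("bandwidths must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class DenseCRFProblem:
    unary: np.ndarray      # (H, W, C) potentials theta_a(x_a)
    positions: np.ndarray  # (H, W, 2) 0-based (row, col) pixel coordinates
    colors: np.ndarray     # (H, W, 3) RGB reals in 0..255

    @property
    def shape(self) -> tuple[int, int]:
        return self.unary.shape[0], self.unary.shape[1]

    @property
    def n_classes(self) -> int:
        return self.unary.shape[2]

    def validate(self) -> None:
        if not np.isfinite(self.unary).all():
            raise ValueError("unary potentials must be finite")
        if self.positions.shape[:2] != self.unary.shape[:2] or self.colors.shape[:2] != self.unary.shape[:2]:
            raise ValueError("positions/colors must align with the unary grid")


@dataclass
class Marginals:
    Q: np.ndarray  # (H, W, C) in [0, 1], rows sum to 1


@dataclass
class Labeling:
    x: np.ndarray  # (H, W) classes


def pixel_grid_positions(h: int, w: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([rr, cc], axis=-1).astype(np.float64)


def unary_from_probabilities(prob: ProbabilityMap | np.ndarray) -> np.ndarray:
    """theta = -log(max(P, eps)); zero cost for certain classes."""
    p = prob.probs if isinstance(prob, ProbabilityMap) else np.asarray(prob, dtype=np.float64)
    return -np.log(np.maximum(p, PROB_EPS))


def problem_from_probabilities(
    prob: ProbabilityMap | np.ndarray, image: np.ndarray
) -> DenseCRFProblem:
    p = prob.probs if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    if image.shape[:2] != p.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} not aligned with probabilities {p.shape[:2]}")
    h, w = p.shape[:2]
    return DenseCRFProblem(
        unary=unary_from_probabilities(prob),
        positions=pixel_grid_positions(h, w),
        colors=np.asarray(image, dtype=np.float64).reshape(h, w, -1)[:, :, :3],
    )


def pairwise_kernel(feat_a: dict, feat_b: dict, params: CRFParams) -> float:
    """k(a, b) for two pixels given as {'p': (row, col), 'I': (r, g, b)}.

    Literal two-kernel form; symmetric and nonnegative by construction.
    """
    dp2 = float(np.sum((np.asarray(feat_a["p"], float) - np.asarray(feat_b["p"], float)) ** 2))
    dI2 = float(np.sum((np.asarray(feat_a["I"], float) - np.asarray(feat_b["I"], float)) ** 2))
    appearance = params.w1 * np.exp(
        -dp2 / (2 * params.sigma_alpha**2) - dI2 / (2 * params.sigma_beta**2)
    )
    smoothness = params.w2 * np.exp(-dp2 / (2 * params.sigma_gamma**2))
    return float(appearance + smoothness)


def kernel_matrix(problem: DenseCRFProblem, params: CRFParams) -> np.ndarray:
    """Dense (N, N) kernel over all pixel pairs (diagonal = w1 + w2)."""
    h, w = problem.shape
    pos = problem.positions.reshape(-1, 2).astype(np.float64)
    col = problem.colors.reshape(-1, 3).astype(np.float64)
    dp2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    dI2 = ((col[:, None, :] - col[None, :, :]) ** 2).sum(-1)
    k = params.w1 * np.exp(-dp2 / (2 * params.sigma_alpha**2) - dI2 / (2 * params.sigma_beta**2))
    k += params.w2 * np.exp(-dp2 / (2 * params.sigma_gamma**2))
    return k


def energy(labeling: Labeling | np.ndarray, problem: DenseCRFProblem, params: CRFParams) -> float:
    """E(x): unary sum plus Potts-weighted kernel over unordered pairs."""
    x = labeling.x if isinstance(labeling, Labeling) else np.asarray(labeling)
    if x.shape != problem.shape:
        raise ValueError(f"labeling {x.shape} does not match problem grid {problem.shape}")
    h, w = problem.shape
    flat = x.ravel()
    un = problem.unary.reshape(-1, problem.n_classes)
    e = float(un[np.arange(flat.size), flat].sum())
    k = kernel_matrix(problem, params)
    disagree = flat[:, None] != flat[None, :]
    e += float((k * disagree)[np.tril_indices(flat.size, k=-1)].sum())
    return e


def mean_field_infer(
    problem: DenseCRFProblem,
    params: CRFParams,
    size_cap: int = DEFAULT_SIZE_CAP,
    update: str = "synchronous",
) -> Marginals:
    """Mean-field marginals Q after ``params.n_iterations`` iterations.

    Q is initialized as softmax(-theta) (the unary distribution).  Each
    iteration recomputes the Potts message m_a(l) = sum_{b != a} k(a,b) *
    (1 - Q_b(l)) and renormalizes Q_a proportional to exp(-theta_a - m_a).
    ``update='synchronous'`` (default) updates all pixels from the previous
    Q; ``'sequential'`` sweeps pixels in raster order using fresh values,
    the variant whose KL objective is monotone.
    """
    problem.validate()
    h, w = problem.shape
    n = h * w
    if n > size_cap:
        raise GridTooLargeError(
            f"grid {h} x {w} ({n} pixels) exceeds the dense-sum cap of {size_cap}; "
            "tile the input (imagery_io.tile_image) or refine a downsampled map"
        )
    if update not in ("synchronous", "sequential"):
        raise ValueError(f"unknown update mode {update!r}")
    theta = problem.unary.reshape(n, -1)
    q = _softmax(-theta)
    k = kernel_matrix(problem, params)
    self_k = np.diag(k).copy()
    if update == "synchronous":
        for _ in range(params.n_iterations):
            m = k @ (1.0 - q) - self_k[:, None] * (1.0 - q)
            q = _softmax(-theta - m)
    else:
        for _ in range(params.n_iterations):
            for a in range(n):
                m_a = k[a] @ (1.0 - q) - self_k[a] * (1.0 - q[a])
                q[a] = _softmax(-theta[a] - m_a)
    return Marginals(Q=q.reshape(h, w, -1))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def map_labeling(marginals: Marginals | np.ndarray) -> Labeling:
    """Per-pixel argmax of Q; ties break toward the lowest class index."""
    q = marginals.Q if isinstance(marginals, Marginals) else np.asarray(marginals)
    return Labeling(x=np.argmax(q, axis=-1))


def exact_map_bruteforce(
    problem: DenseCRFProblem, params: CRFParams, max_states: int = 10**6
) -> tuple[Labeling, float]:
    """Exhaustive energy minimizer for tiny problems (C^N states).

    Ties break toward the lexicographically smallest labeling; the search
    enumerates labelings in lexicographic order and keeps the first minimum.
    """
    h, w = problem.shape
    n = h * w
    c = problem.n_classes
    if c**n > max_states:
        raise ValueError(f"instance too large for brute force: {c}^{n} > {max_states}")
    un = problem.unary.reshape(n, c)
    k = kernel_matrix(problem, params)
    pairs = [(a, b) for a in range(n) for b in range(a)]
    best_x, best_e = None, np.inf
    for assign in itertools.product(range(c), repeat=n):
        e = sum(un[i, l] for i, l in enumerate(assign))
        for a, b in pairs:
            if assign[a] != assign[b]:
                e += k[a, b]
        if e < best_e:
            best_e, best_x = e, assign
    return Labeling(x=np.asarray(best_x).reshape(h, w)), float(best_e)


def crf_refine(
    prob: ProbabilityMap | np.ndarray,
    image: np.ndarray,
    params: CRFParams,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> Labeling:
    """Full refinement: probabilities -> unaries -> mean field -> argmax."""
    problem = problem_from_probabilities(prob, image)
    marg = mean_field_infer(problem, params, size_cap=size_cap)
    return map_labeling(marg)


DEFAULT_GRID = {
    "w1": (1.0, 2.0, 5.0, 10.0),
    "sigma_alpha": (3.0, 10.0, 30.0),
    "sigma_beta": (3.0, 10.0, 30.0),
}


def grid_search_crf(
    train_set,
    candidates: dict | None = None,
    metric: str = "mean_iu",
    base_params: CRFParams | None = None,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> tuple[CRFParams, pd.DataFrame]:
    """Exhaustive search over (w1, sigma_alpha, sigma_beta) on a training set.

    ``train_set`` is a sequence of (prob, image, gt) triples.  Returns the
    best parameters by the pooled metric (ties to the first candidate in
    declared grid order) and the full score table.
    """
    from .evaluation import confusion, metrics as compute_metrics

    if metric not in ("mean_iu", "overall_accuracy", "kappa"):
        raise ValueError(f"unknown metric {metric!r}")
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty training set")
    grid = candidates or DEFAULT_GRID
    base = base_params or CRFParams()
    rows = []
    best_params, best_score = None, -np.inf
    for w1 in grid["w1"]:
        for sa in grid["sigma_alpha"]:
            for sb in grid["sigma_beta"]:
                params = replace(base, w1=float(w1), sigma_alpha=float(sa), sigma_beta=float(sb))
                preds, gts = [], []
                for prob, image, gt in train_set:
                    preds.append(crf_refine(prob, image, params, size_cap=size_cap).x)
                    gts.append(gt)
                rep = compute_metrics(confusion(gts, preds))
                score = getattr(rep, metric)
                rows.append(
                    {
                        "w1": w1, "sigma_alpha": sa, "sigma_beta": sb,
                        "mean_iu": rep.mean_iu,
                        "overall_accuracy": rep.overall_accuracy,
                        "kappa": rep.kappa,
                    }
                )
                if score > best_score:
                    best_score, best_params = score, params
    return best_params, pd.DataFrame(rows)
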