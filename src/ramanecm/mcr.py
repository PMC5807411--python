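"""Non-negativity-constrained multivariate curve resolution (MCR-ALS).

Factorizes the pixel matrix D (n_pixels x n_channels) of a cube cropped
to the biomolecularly specific fingerprint range as

    D = C S + E,      C >= 0,  S >= 0,

with C the per-pixel relative concentrations, S the pure component
spectra and E the residuals, by alternating exact non-negative least
squares on C (pixel-wise) and S (channel-wise). Rows of S are kept at
unit Euclidean norm so concentrations carry all magnitude; this fixes
the intrinsic scale ambiguity of bilinear models. The residual
Frobenius norm is non-increasing across iterations (each half-step is
an exact constrained minimizer).

Orientation effects in strongly aligned matrices can split one chemical
species into several near-identical ("degenerate") components;
:func:`merge_degenerate` sums their concentration maps back into one.
Resolved spectra are identified against reference spectra of the pure
biochemicals with :func:`match_references`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls as _scipy_nnls

from .spectral import HyperspectralCube, WavenumberAxis, crop_range

__all__ = [
    "ComponentSpectra",
    "ConcentrationMaps",
    "MCRResult",
    "MCROptions",
    "ReferenceMatch",
    "init_components",
    "nnls_solve",
    "fit_mcr",
    "merge_degenerate",
    "match_references",
]

logger = logging.getLogger(__name__)

FINGERPRINT_RANGE = (800.0, 1800.0)


@dataclass(frozen=True)
class ComponentSpectra:
    """k x n_channels matrix of pure (resolved or reference) spectra."""

    spectra: np.ndarray
    names: tuple[str, ...]
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "names", tuple(self.names))
        if spectra.shape != (len(self.names), len(self.axis)):
            raise ValueError(
                f"spectra shape {spectra.shape} inconsistent with "
                f"{len(self.names)} names and {len(self.axis)} channels"
            )
        if np.any(spectra < 0):
            raise ValueError("component spectra must be non-negative")

    @property
    def k(self) -> int:
        return self.spectra.shape[0]


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-component abundance images (matrix C reshaped), in a.u."""

    maps: np.ndarray  # k x rows x cols
    names: tuple[str, ...]
    pixel_size_um: float = 10.0

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim == 2:
            maps = maps[None, ...]
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "names", tuple(self.names))
        if maps.ndim != 3 or maps.shape[0] != len(self.names):
            raise ValueError("maps must be k x rows x cols with one name per map")
        if np.any(maps < 0):
            raise ValueError("concentration maps must be non-negative")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def get(self, name: str) -> np.ndarray:
        return self.maps[self.names.index(name)]

    def to_matrix(self) -> np.ndarray:
        """C as n_pixels x k (rows-then-columns pixel order)."""
        return self.maps.reshape(self.k, -1).T


@dataclass
class MCRResult:
    S: ComponentSpectra
    C: ConcentrationMaps
    explained_variance_total: float
    explained_variance_per_component: np.ndarray
    n_iterations: int
    converged: bool
    residual_norm: float
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass(frozen=True)
class MCROptions:
    max_iter: int = 200
    tol: float = 1e-6
    init: str = "purest_pixel"  # purest_pixel | seeded_random
    seed: int = 0
    fit_range: tuple[float, float] | None = FINGERPRINT_RANGE
    #: optional initial spectral estimates (k x n_channels), e.g.
    #: reference spectra of the expected pure biochemicals — the
    #: standard chemometric initialization when references exist;
    #: overrides ``init`` when given
    init_spectra: np.ndarray | None = None


def nnls_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares: argmin ||Ax - b||, x >= 0.

    Lawson-Hanson active-set solution (not a projection of the
    unconstrained solution). All-zero columns of A get coefficient 0.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.shape != (A.shape[0],):
        raise ValueError(f"incompatible shapes {A.shape} and {b.shape}")
    x, _ = _scipy_nnls(A, b)
    return x


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise NNLS, min ||A X - B||_F with X >= 0.

    Fast path: solve unconstrained least squares for all columns at
    once; where the solution is already in the non-negative orthant it
    is the exact NNLS solution, and only violating columns fall back to
    the active-set solver.
    """
    X, *_ = np.linalg.lstsq(A, B, rcond=None)
    bad = np.flatnonzero(np.any(X < -1e-10, axis=0))
    for j in bad:
        X[:, j], _ = _scipy_nnls(A, B[:, j])
    np.clip(X, 0.0, None, out=X)
    return X


def init_components(
    D: np.ndarray, k: int, method: str = "purest_pixel", seed: int = 0,
    axis: WavenumberAxis | None = None, names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Initial k x n_channels non-negative unit-norm spectral estimates.

    ``purest_pixel`` starts from the most intense pixel spectrum and
    greedily adds the pixel most dissimilar from the span of those
    already chosen (largest orthogonal residual of the normalized
    spectrum — a determinant/purity criterion). Deterministic.
    ``seeded_random`` picks k distinct random pixels.
    """
    D = np.asarray(D, dtype=float)
    n_pix, n_chan = D.shape
    if not 1 <= k <= min(n_pix, n_chan):
        raise ValueError(f"k={k} infeasible for D of shape {D.shape}")
    if method == "seeded_random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_pix, size=k, replace=False)
    elif method == "purest_pixel":
        norms = np.linalg.norm(D, axis=1)
        idx = [int(np.argmax(norms))]
        unit = D / np.maximum(norms, 1e-300)[:, None]
        Q = np.empty((0, n_chan))
        for _ in range(1, k):
            q_new = unit[idx[-1]] - Q.T @ (Q @ unit[idx[-1]])
            nrm = np.linalg.norm(q_new)
            if nrm > 1e-12:
                Q = np.vstack([Q, q_new / nrm])
            resid = unit - (unit @ Q.T) @ Q
            score = np.linalg.norm(resid, axis=1)
            score[idx] = -1.0
            idx.append(int(np.argmax(score)))
        idx = np.asarray(idx)
    else:
        raise ValueError(f"unknown init method {method!r}")
    S = np.maximum(D[idx], 0.0)
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise ValueError("selected an all-zero pixel spectrum for initialization")
    return S / norms[:, None]


def _normalize_rows(S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(S, axis=1)
    norms[norms == 0] = 1.0
    return S / norms[:, None], C * norms[None, :]


def fit_mcr(
    cube: HyperspectralCube | list[HyperspectralCube],
    k: int = 4,
    opts: MCROptions | None = None,
) -> MCRResult | tuple[MCRResult, list[ConcentrationMaps]]:
    """Resolve a cube (or several cubes jointly) into k components.

    Several cubes are concatenated into one pixel matrix and share one
    S ("analyzed together"); the return value is then ``(result,
    per_cube_maps)`` where ``result.C`` holds the first cube's maps.
    """
    opts = opts or MCROptions()
    cubes = cube if isinstance(cube, list) else [cube]
    if opts.fit_range is not None:
        lo, hi = opts.fit_range
        cubes = [
            crop_range(c, lo, hi)
            if (c.axis.values[0] < lo or c.axis.values[-1] > hi) else c
            for c in cubes
        ]
    axis = cubes[0].axis
    for c in cubes[1:]:
        if not np.array_equal(c.axis.values, axis.values):
            raise ValueError("cubes must share a wavenumber axis after cropping")
    D = np.vstack([c.to_matrix() for c in cubes])
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite intensities in D")

    if opts.init_spectra is not None:
        S0 = np.atleast_2d(np.asarray(opts.init_spectra, dtype=float))
        if S0.shape[0] > k or S0.shape[1] != D.shape[1]:
            raise ValueError(
                f"init_spectra shape {S0.shape} incompatible with k={k} and "
                f"{D.shape[1]} channels"
            )
        S = np.maximum(S0, 0.0)
        S = S / np.linalg.norm(S, axis=1, keepdims=True)
        if S0.shape[0] < k:  # top up with purest pixels
            extra = init_components(D, k - S0.shape[0], "purest_pixel", opts.seed)
            S = np.vstack([S, extra])
    else:
        S = init_components(D, k, opts.init, opts.seed)
    d_norm2 = float(np.sum(D * D))
    history: list[float] = []
    C = None
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # C-step: per-pixel NNLS against current S
        C = _nnls_columns(S.T, D.T).T
        # S-step: per-channel NNLS against current C
        S = _nnls_columns(C, D)
        S, C = _normalize_rows(S, C)
        resid = float(np.linalg.norm(D - C @ S))
        history.append(resid)
        logger.info("mcr iteration %d: residual %.6g", it, resid)
        if resid <= 1e-7 * np.sqrt(d_norm2):
            converged = True  # exact factorization reached
            break
        if len(history) > 1:
            prev = history[-2]
            if abs(prev - resid) <= opts.tol * max(prev, 1e-300):
                converged = True
                break
    if not converged:
        logger.warning("MCR-ALS did not converge in %d iterations", opts.max_iter)

    # final concentration refresh so C is exactly the per-pixel NNLS
    # solution against the returned S
    C = _nnls_columns(S.T, D.T).T
    resid_norm = float(np.linalg.norm(D - C @ S))
    history.append(resid_norm)
    ev_total = 100.0 * (1.0 - resid_norm**2 / d_norm2)
    ev_comp = np.array([
        100.0 * np.sum(np.outer(C[:, j], S[j]) ** 2) / d_norm2 for j in range(k)
    ])
    names = tuple(f"component_{j}" for j in range(k))
    S_out = ComponentSpectra(S, names, axis)

    # split concentrations back per cube
    offsets = np.cumsum([0] + [c.n_pixels for c in cubes])
    per_cube = []
    for i, c in enumerate(cubes):
        block = C[offsets[i]: offsets[i + 1]]
        per_cube.append(ConcentrationMaps(
            block.T.reshape(k, c.n_rows, c.n_cols), names, c.pixel_size_um
        ))
    result = MCRResult(
        S=S_out,
        C=per_cube[0],
        explained_variance_total=float(ev_total),
        explained_variance_per_component=ev_comp,
        n_iterations=it,
        converged=converged,
        residual_norm=resid_norm,
        residual_history=np.asarray(history),
    )
    if isinstance(cube, list):
        return result, per_cube
    return result


def _correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of A with every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    an = np.linalg.norm(Ac, axis=1)
    bn = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(an, bn)
    return np.nan_to_num(r, nan=0.0)


def merge_degenerate(result: MCRResult, r_threshold: float = 0.9) -> MCRResult:
    """Sum components whose pure spectra correlate at r >= threshold.

    Groups are the transitive closure of the pairwise criterion. The
    merged concentration map is the element-wise sum; the merged
    spectrum is the total-concentration-weighted mean of the member
    spectra, renormalized to unit norm.
    """
    S = result.S.spectra
    k = S.shape[0]
    r = _correlation_matrix(S, S)
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if r[i, j] >= r_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    if len(groups) == k:
        return result

    C = result.C.to_matrix()
    weights = C.sum(axis=0)
    new_S, new_C, new_names = [], [], []
    for members in sorted(groups.values(), key=min):
        if len(members) == 1:
            j = members[0]
            new_S.append(S[j])
            new_C.append(C[:, j])
            new_names.append(result.S.names[j])
        else:
            w = weights[members]
            w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
            s = w @ S[members]
            nrm = np.linalg.norm(s)
            new_S.append(s / nrm if nrm > 0 else s)
            new_C.append(C[:, members].sum(axis=1))
            new_names.append(result.S.names[members[int(np.argmax(w))]])
    S_new = np.vstack(new_S)
    C_new = np.stack(new_C, axis=1)
    k_new = S_new.shape[0]
    rows, cols = result.C.maps.shape[1:]
    maps = ConcentrationMaps(
        C_new.T.reshape(k_new, rows, cols), tuple(new_names), result.C.pixel_size_um
    )
    spectra = ComponentSpectra(S_new, tuple(new_names), result.S.axis)
    return replace(result, S=spectra, C=maps)


@dataclass(frozen=True)
class ReferenceMatch:
    spectra: ComponentSpectra  # S relabelled with matched reference names
    r_squared: dict[str, float]  # reference name -> squared Pearson r
    assignment: dict[int, str]  # S row index -> assigned label


def match_references(S: ComponentSpectra, refs: ComponentSpectra) -> ReferenceMatch:
    """Optimal one-to-one identification of resolved spectra.

    References on a different axis are linearly resampled onto S's
    axis. The assignment maximizes the total Pearson correlation
    (Hungarian algorithm); components left over when k exceeds the
    number of references are labelled ``residual``.
    """
    ref_spectra = refs.spectra
    if not np.array_equal(refs.axis.values, S.axis.values):
        ref_spectra = np.stack([
            np.interp(S.axis.values, refs.axis.values, row) for row in ref_spectra
        ])
    r = _correlation_matrix(S.spectra, ref_spectra)
    rows, cols = linear_sum_assignment(-r)
    assignment: dict[int, str] = {}
    r2: dict[str, float] = {}
    for i, j in zip(rows, cols):
        assignment[int(i)] = refs.names[j]
        r2[refs.names[j]] = float(r[i, j] ** 2)
    n_residual = 0
    names = []
    for i in range(S.k):
        if i in assignment:
            names.append(assignment[i])
        else:
            label = "residual" if n_residual == 0 else f"residual_{n_residual}"
            n_residual += 1
            assignment[i] = label
            names.append(label)
    relabelled = ComponentSpectra(S.spectra, tuple(names), S.axis)
    return ReferenceMatch(relabelled, r2, assignment)
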