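"""Pearson correlation matrix, random-matrix-theory (RMT) threshold
selection, and co-expression network construction.

The RMT criterion exploits a universal property of random symmetric
matrices: the nearest-neighbor spacing distribution (NNSD) of unfolded
eigenvalues follows the Wigner surmise, P(s) = (pi s / 2) exp(-pi s^2 / 4),
for a Gaussian orthogonal ensemble (GOE), whereas a superposition of
independent blocks — a genuinely modular system — follows the Poisson law
P(s) = exp(-s).  Scanning the correlation cutoff upward, the thresholded
matrix transitions from GOE-like (noise links mix the modules) to Poisson
(modules decouple); the selected cutoff is the smallest one at which the
Poisson hypothesis is accepted and stays accepted for all denser cutoffs in
the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .io import ExpressionMatrix

DEFAULT_MIN_PAIRS = 9
DEFAULT_MIN_EIGS = 100
DEFAULT_P_ACCEPT = 1e-3
DEGENERACY_TOL = 1e-8

#: Spacing histogram window and bin count for the chi-square NNSD tests.
NNSD_S_MAX = 3.0
NNSD_BINS = 20


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlations over unmasked sample pairs.

    ``usable[i, j]`` is False where fewer than ``min_pairs`` mutually
    quantifiable samples were available or a gene had zero variance over
    them; unusable pairs never become edges.
    """

    genes: list[str]
    r: np.ndarray
    n_pairs: np.ndarray
    usable: np.ndarray
    min_pairs: int

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def pearson_matrix(x: ExpressionMatrix, min_pairs: int = DEFAULT_MIN_PAIRS) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between all gene pairs.

    Masked cells are excluded pairwise; pairs with fewer than ``min_pairs``
    shared quantifiable samples, or with a zero-variance member over the
    shared samples, are flagged unusable rather than propagating NaN.
    Implemented with masked matrix products, O(n_genes^2 * n_samples).
    """
    if x.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    m = x.mask.astype(float)
    vals = np.where(x.mask, x.values, 0.0)
    n = m @ m.T
    sx = vals @ m.T           # sum of x over the joint mask, rows = x-gene
    sxx = (vals * vals) @ m.T
    sxy = vals @ vals.T
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.maximum(n, 1.0)
        mean_x = sx / n_safe
        mean_y = mean_x.T
        cov = sxy / n_safe - mean_x * mean_y
        var_x = sxx / n_safe - mean_x**2
        var_y = var_x.T
        denom = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
        r = cov / denom
    usable = (n >= min_pairs) & (denom > 0) & np.isfinite(r)
    r = np.where(usable, r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(usable, True)
    return CorrelationMatrix(
        genes=list(x.genes),
        r=r,
        n_pairs=n.astype(int),
        usable=usable,
        min_pairs=min_pairs,
    )


# ---------------------------------------------------------------------------
# nearest-neighbor spacing statistics


class TooFewEigenvaluesError(ValueError):
    """Spectrum too small for spacing statistics after degeneracy removal."""


@dataclass
class NnsdResult:
    unfolded_spacings: np.ndarray
    chi2_poisson: float
    chi2_goe: float
    p_poisson: float
    p_goe: float
    n_eigenvalues: int


def _dedupe(eigs: np.ndarray, tol: float = DEGENERACY_TOL) -> np.ndarray:
    """Keep one eigenvalue per near-degenerate cluster (|delta| < tol)."""
    eigs = np.sort(np.asarray(eigs, dtype=float))
    if eigs.size == 0:
        return eigs
    keep = [eigs[0]]
    for e in eigs[1:]:
        if e - keep[-1] >= tol:
            keep.append(e)
    return np.array(keep)


def unfold_eigenvalues(eigs: np.ndarray, knots_divisor: int = 20) -> np.ndarray:
    """Map sorted eigenvalues to unit mean spacing via a monotone smooth of
    the empirical spectral CDF.

    A PCHIP (monotone cubic) interpolant is fitted through ~n/knots_divisor
    support points of the empirical CDF and evaluated at every eigenvalue;
    the images, scaled by n, have mean spacing ~1.
    """
    eigs = np.sort(np.asarray(eigs, dtype=float))
    n = eigs.size
    if n < 5:
        raise TooFewEigenvaluesError(f"cannot unfold {n} eigenvalues")
    n_knots = max(5, n // knots_divisor)
    idx = np.unique(np.linspace(0, n - 1, n_knots).round().astype(int))
    # midpoint plotting positions avoid 0/1 endpoints of the ECDF
    cdf = (idx + 0.5) / n
    xk, yk = eigs[idx], cdf
    # PCHIP needs strictly increasing x; collapse residual coincidences
    keep = np.concatenate([[True], np.diff(xk) > 0])
    fhat = PchipInterpolator(xk[keep], yk[keep], extrapolate=True)
    unfolded = n * np.clip(fhat(eigs), 0.0, 1.0)
    return unfolded


def _chi2_against(spacings: np.ndarray, cdf, n_bins: int, s_max: float) -> tuple[float, float, int]:
    """Chi-square of the spacing histogram against a reference law.

    Expected bin probabilities are renormalized to the [0, s_max] window so
    observed and expected totals match; bins with expected count < 5 are
    merged from the right; dof = used bins - 1.
    """
    in_range = spacings[(spacings >= 0) & (spacings <= s_max)]
    n_obs = in_range.size
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(in_range, bins=edges)
    p = np.diff(cdf(edges))
    total = cdf(s_max) - cdf(0.0)
    p = p / total
    exp = n_obs * p

    # merge under-filled bins into their left neighbour, starting at the tail
    obs_list, exp_list = list(obs.astype(float)), list(exp)
    i = len(exp_list) - 1
    while i > 0:
        if exp_list[i] < 5.0:
            exp_list[i - 1] += exp_list[i]
            obs_list[i - 1] += obs_list[i]
            del exp_list[i], obs_list[i]
        i -= 1
    obs_a, exp_a = np.array(obs_list), np.array(exp_list)
    chi2 = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    dof = max(len(exp_a) - 1, 1)
    p_val = float(stats.chi2.sf(chi2, dof))
    return chi2, p_val, dof


def _poisson_cdf(s):
    return 1.0 - np.exp(-np.asarray(s, dtype=float))


def _wigner_cdf(s):
    s = np.asarray(s, dtype=float)
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def nnsd_statistics(
    eigenvalues: np.ndarray,
    min_eigs: int = DEFAULT_MIN_EIGS,
    n_bins: int = NNSD_BINS,
    s_max: float = NNSD_S_MAX,
) -> NnsdResult:
    """Unfolded nearest-neighbor spacing statistics of a spectrum.

    Near-degenerate eigenvalues (spacing < 1e-8) are collapsed first — large
    zero-eigenvalue multiplicities from isolated nodes would otherwise pile
    spacing mass at 0.  Returns chi-square goodness-of-fit against the
    Poisson law exp(-s) and the Wigner surmise (pi s/2) exp(-pi s^2/4).
    """
    eigs = _dedupe(eigenvalues)
    if eigs.size < min_eigs:
        raise TooFewEigenvaluesError(
            f"only {eigs.size} distinct eigenvalues (< {min_eigs}); "
            "use a denser matrix or a lower cutoff"
        )
    unfolded = unfold_eigenvalues(eigs)
    spacings = np.diff(unfolded)
    chi2_p, p_p, _ = _chi2_against(spacings, _poisson_cdf, n_bins, s_max)
    chi2_g, p_g, _ = _chi2_against(spacings, _wigner_cdf, n_bins, s_max)
    return NnsdResult(
        unfolded_spacings=spacings,
        chi2_poisson=chi2_p,
        chi2_goe=chi2_g,
        p_poisson=p_p,
        p_goe=p_g,
        n_eigenvalues=int(eigs.size),
    )


# ---------------------------------------------------------------------------
# threshold scan and network construction


def default_tau_grid() -> np.ndarray:
    return np.round(np.arange(0.70, 0.995, 0.01), 2)


def _threshold_adjacency(c: CorrelationMatrix, tau: float, mode: str, binary: bool) -> np.ndarray:
    if mode == "abs":
        keep = (np.abs(c.r) >= tau) & c.usable
    elif mode == "positive":
        keep = (c.r >= tau) & c.usable
    else:
        raise ValueError(f"mode must be 'abs' or 'positive', got {mode!r}")
    a = np.where(keep, 1.0 if binary else c.r, 0.0)
    np.fill_diagonal(a, 0.0)
    return a


@dataclass
class ThresholdScan:
    """Per-candidate spectral statistics of the cutoff scan."""

    candidates: np.ndarray
    n_edges: np.ndarray
    n_eigenvalues: np.ndarray
    chi2_poisson: np.ndarray
    chi2_goe: np.ndarray
    p_poisson: np.ndarray
    selected_tau: float
    selected_index: int
    accepted: np.ndarray
    evaluable: np.ndarray
    warning: bool
    #: False when the first evaluable candidate is already accepted — the
    #: Poisson transition then lies below the grid and the selected cutoff
    #: is only an upper bracket of it.
    transition_bracketed: bool
    mode: str
    eigenvalues: list[np.ndarray] = field(default_factory=list)
    unfolded_spacings: list[np.ndarray] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tau": self.candidates,
                "n_edges": self.n_edges,
                "n_eigenvalues": self.n_eigenvalues,
                "chi2_poisson": self.chi2_poisson,
                "chi2_goe": self.chi2_goe,
                "p_poisson": self.p_poisson,
                "accepted": self.accepted,
                "selected": [i == self.selected_index for i in range(len(self.candidates))],
            }
        )


def rmt_threshold_scan(
    c: CorrelationMatrix,
    tau_grid: np.ndarray | None = None,
    mode: str = "abs",
    p_accept: float = DEFAULT_P_ACCEPT,
    min_eigs: int = DEFAULT_MIN_EIGS,
    binary: bool = False,
    keep_spectra: bool = False,
) -> ThresholdScan:
    """Scan correlation cutoffs and select the Poisson-transition cutoff.

    For each candidate the thresholded (weighted, by default) adjacency
    restricted to non-isolated genes is eigendecomposed and its NNSD tested
    against the Poisson law.  Selected cutoff: the smallest candidate whose
    Poisson fit is accepted (p > p_accept) with no GOE-leaning rejection at
    any larger candidate (the stability guard against isolated false
    acceptances); candidates with too few distinct eigenvalues are recorded
    as unevaluable (NaN) and skipped.  If no candidate qualifies, the
    largest candidate is returned with ``warning=True``.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("empty cutoff grid")
    if np.any(np.diff(tau_grid) <= 0) or tau_grid[0] <= 0 or tau_grid[-1] >= 1:
        raise ValueError("cutoff grid must be strictly ascending within (0, 1)")

    k = tau_grid.size
    n_edges = np.zeros(k, dtype=int)
    n_eigs = np.zeros(k, dtype=int)
    chi2_p = np.full(k, np.nan)
    chi2_g = np.full(k, np.nan)
    p_p = np.full(k, np.nan)
    spectra: list[np.ndarray] = []
    spacings: list[np.ndarray] = []

    for i, tau in enumerate(tau_grid):
        a = _threshold_adjacency(c, tau, mode, binary)
        deg = (a != 0).sum(axis=1)
        connected = deg > 0
        n_edges[i] = int((a != 0).sum() // 2)
        sub = a[np.ix_(connected, connected)]
        if sub.shape[0] == 0:
            spectra.append(np.empty(0))
            spacings.append(np.empty(0))
            continue
        eigs = np.linalg.eigvalsh(sub)
        try:
            res = nnsd_statistics(eigs, min_eigs=min_eigs)
        except TooFewEigenvaluesError:
            n_eigs[i] = _dedupe(eigs).size
            spectra.append(eigs if keep_spectra else np.empty(0))
            spacings.append(np.empty(0))
            continue
        n_eigs[i] = res.n_eigenvalues
        chi2_p[i] = res.chi2_poisson
        chi2_g[i] = res.chi2_goe
        p_p[i] = res.p_poisson
        spectra.append(eigs if keep_spectra else np.empty(0))
        spacings.append(res.unfolded_spacings if keep_spectra else np.empty(0))

    evaluable = np.isfinite(p_p)
    accepted = evaluable & (p_p > p_accept)
    # A Poisson rejection vetoes lower candidates only when the spectrum
    # leans toward GOE (mixing).  Near-fully-fragmented graphs at the top of
    # the grid can reject Poisson in the opposite direction — repeated
    # small-motif spectra cluster their eigenvalue spacings — and that
    # breakdown of the statistic says nothing about modular structure below.
    blocking = evaluable & ~accepted & (chi2_g < chi2_p)

    selected_index = -1
    for i in range(k):
        if not evaluable[i]:
            continue
        if accepted[i] and not blocking[i:].any():
            selected_index = i
            break
    warning = selected_index < 0
    if warning:
        selected_index = k - 1
        warnings.warn(
            "no cutoff passed the Poisson-acceptance stability rule; "
            "returning the largest candidate",
            stacklevel=2,
        )
    first_evaluable = int(np.argmax(evaluable)) if evaluable.any() else -1
    transition_bracketed = bool(
        first_evaluable >= 0 and not accepted[first_evaluable]
    )
    return ThresholdScan(
        candidates=tau_grid,
        n_edges=n_edges,
        n_eigenvalues=n_eigs,
        chi2_poisson=chi2_p,
        chi2_goe=chi2_g,
        p_poisson=p_p,
        selected_tau=float(tau_grid[selected_index]),
        selected_index=selected_index,
        accepted=accepted,
        evaluable=evaluable,
        warning=warning,
        transition_bracketed=transition_bracketed,
        mode=mode,
        eigenvalues=spectra,
        unfolded_spacings=spacings,
    )


def group_correlation_boundary(
    c: CorrelationMatrix,
    group_of: dict[str, str | None],
    tau_grid: np.ndarray | None = None,
    mode: str = "abs",
) -> tuple[float, float]:
    """Empirical boundary separating within-group from other correlations.

    ``group_of`` maps genes to planted-module labels (None = background).
    Returns ``(boundary_tau, max_between_r)`` where ``max_between_r`` is the
    largest correlation magnitude among usable pairs that are not inside one
    planted module, and ``boundary_tau`` is the smallest grid cutoff
    strictly above it — the lowest cutoff at which the thresholded network
    contains no between-group link.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    labels = np.array([group_of.get(g) for g in c.genes], dtype=object)
    planted = labels != None  # noqa: E711 — elementwise against object array
    same = (labels[:, None] == labels[None, :]) & planted[:, None] & planted[None, :]
    iu = np.triu_indices(c.n_genes, 1)
    between = ~same[iu] & c.usable[iu]
    vals = c.r[iu][between]
    max_between = float(np.max(np.abs(vals) if mode == "abs" else vals))
    above = tau_grid[tau_grid > max_between]
    boundary = float(above[0]) if above.size else float(tau_grid[-1])
    return boundary, max_between


@dataclass
class CoexpressionNetwork:
    """Undirected signed-edge co-expression graph at one cutoff.

    Nodes are genes with at least one link; each edge carries the
    correlation ``r`` and its sign.  Backed by a networkx Graph.
    """

    graph: nx.Graph
    tau: float
    mode: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_dataframe(self):
        import pandas as pd

        rows = [
            {"gene_a": min(u, v), "gene_b": max(u, v), "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])
        return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    def degree_series(self):
        import pandas as pd

        return pd.Series(dict(self.graph.degree), name="degree").sort_index()


def build_network(c: CorrelationMatrix, tau: float, mode: str = "positive") -> CoexpressionNetwork:
    """Threshold the correlation matrix into a co-expression network.

    ``mode='positive'`` keeps pairs with r >= tau (the reported-network
    convention); ``mode='abs'`` keeps |r| >= tau and records the sign.
    Isolated genes are not part of the node set.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    a = _threshold_adjacency(c, tau, mode, binary=False)
    g = nx.Graph(tau=tau, mode=mode)
    ii, jj = np.nonzero(np.triu(a, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        r = float(c.r[i, j])
        g.add_edge(c.genes[i], c.genes[j], r=r, sign="+" if r > 0 else "-")
    return CoexpressionNetwork(graph=g, tau=float(tau), mode=mode)
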