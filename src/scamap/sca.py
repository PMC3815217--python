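"""Conservation and statistical coupling analysis (SCA) of protein alignments.

SCA detects groups of co-evolving alignment positions ("sectors") from the
spectrum of a conservation-weighted positional covariance matrix.  The
pipeline implemented here is:

1.  *Sequence weighting* — each row is down-weighted by its number of
    neighbors at >= 80% identity, so dense clades do not dominate.
2.  *Regularized frequencies* — weighted positional frequencies
    ``f_i^a`` and pairwise frequencies ``f_ij^ab`` with a small pseudocount
    mixed toward a background composition ``q``:
    ``f = (1 - lam) * f_raw + lam * q``.
3.  *Conservation weighting* — the positional derivative of relative
    entropy, ``phi_i^a = ln[ f_i^a (1 - q_a) / (q_a (1 - f_i^a)) ]``.
4.  *Coupling matrix* — the amino-acid-resolved covariance
    ``C_ij^ab = f_ij^ab - f_i^a f_j^b`` is phi-weighted and compressed to a
    single positive magnitude per position pair (Frobenius norm over the
    two amino-acid dimensions).
5.  *Spectral significance* — eigenvalues of the coupling matrix are
    compared against null spectra from alignments with every column
    independently permuted across rows; modes above the null band are kept.
6.  *ICA* — the significant eigenvectors are rotated by a fixed-point
    independent component analysis toward sparse, independent loading
    patterns; sectors are the positions with outlier loadings on each
    component.

The model/results split follows the fitted-model convention: ``SCA`` holds
the alignment and hyper-parameters, ``SCA.fit`` runs steps 1-6 and returns
an ``SCAResults`` carrying the matrices, spectra, sectors and a ``summary()``
table.  Each step is also available as a standalone function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, ReferenceMap, _identity_matrix
from .constants import (
    AA_ALPHABET,
    AA_INDEX,
    BACKGROUND_COMPOSITION,
    DEFAULT_PSEUDOCOUNT,
    GAP_CODE,
)

__all__ = [
    "sequence_weights",
    "WeightedFrequencies",
    "weighted_frequencies",
    "relative_entropy_profile",
    "ConservationProfile",
    "sca_matrix",
    "spectral_modes",
    "SpectralModes",
    "ica_rotation",
    "ICAResult",
    "Sector",
    "SectorSet",
    "extract_sectors",
    "sector_overlap",
    "CooccurrenceTable",
    "cooccurrence_table",
    "perturbation_profile",
    "SCA",
    "SCAResults",
]


# ---------------------------------------------------------------------------
# Weights and frequencies


def background_from_alignment(
    alignment: Alignment, weights: np.ndarray | None = None
) -> np.ndarray:
    """Estimate a background composition from the alignment itself
    (weighted residue counts over all non-gap cells, normalized)."""
    idx = alignment.to_indices()
    if weights is None:
        weights = np.ones(alignment.n_seq)
    weights = np.asarray(weights, dtype=float)
    counts = np.zeros(20)
    for a in range(20):
        counts[a] = (weights[:, None] * (idx == a)).sum()
    if counts.sum() == 0:
        raise ValueError("alignment contains no residues")
    return counts / counts.sum()


def sequence_weights(alignment: Alignment, neighbor_identity: float = 0.8) -> np.ndarray:
    """Inverse-neighbor-count sequence weights.

    ``w_s = 1 / |{t : identity(s, t) >= neighbor_identity}|`` with the
    sequence itself included, so weights lie in (0, 1].  Identity is counted
    over columns where both rows are non-gap.  The effective number of
    sequences is ``weights.sum()``.
    """
    if alignment.n_seq == 0:
        raise ValueError("empty alignment")
    ident = _identity_matrix(alignment.to_indices())
    neighbors = (ident >= neighbor_identity - 1e-12).sum(axis=1)
    return 1.0 / neighbors


def _onehot(idx: np.ndarray) -> np.ndarray:
    """(n, p, 20) indicator array; gap rows contribute nothing."""
    n, p = idx.shape
    oh = np.zeros((n, p, 20), dtype=np.float64)
    rows, cols = np.nonzero(idx != GAP_CODE)
    oh[rows, cols, idx[rows, cols]] = 1.0
    return oh


@dataclass
class WeightedFrequencies:
    """Regularized weighted frequencies and conservation weights.

    Attributes
    ----------
    fi : ndarray (p, 20)
        Regularized positional frequencies; ``fi[i].sum()`` may fall short of
        1 by the (down-weighted) gap mass of the column.
    phi : ndarray (p, 20)
        Conservation weights ``ln[f(1-q)/(q(1-f))]``.
    """

    weights: np.ndarray
    background: np.ndarray
    pseudocount: float
    fi: np.ndarray
    _onehot_flat: np.ndarray = field(repr=False)

    @property
    def n_positions(self) -> int:
        return self.fi.shape[0]

    @property
    def effective_sequences(self) -> float:
        return float(self.weights.sum())

    @property
    def phi(self) -> np.ndarray:
        # clipped so fully conserved columns at pseudocount 0 stay finite;
        # their covariance is exactly 0, so the product is unaffected
        f = np.clip(self.fi, 1e-12, 1 - 1e-12)
        q = self.background
        return np.log(f * (1 - q) / (q * (1 - f)))

    def pairwise(self) -> np.ndarray:
        """Regularized pairwise frequencies, shape (p, 20, p, 20).

        Counts use rows that are non-gap at both positions; the pseudocount
        mixes every block, including i = j, toward ``q_a q_b``.  The raw
        diagonal blocks are ``delta_ab raw_i^a``, so the mixed table stays
        consistent with the positional marginals and a duplicated column
        couples to its copy exactly as to itself.
        """
        X = self._onehot_flat
        w = self.weights
        p = self.n_positions
        lam, q = self.pseudocount, self.background
        raw = (X.T * w) @ X / w.sum()  # (20p, 20p)
        raw = raw.reshape(p, 20, p, 20)
        prior = np.einsum("a,b->ab", q, q)[None, :, None, :]
        return (1 - lam) * raw + lam * np.broadcast_to(prior, raw.shape)


def weighted_frequencies(
    alignment: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> WeightedFrequencies:
    """Compute regularized positional frequencies for an alignment."""
    if not 0 <= pseudocount < 1:
        raise ValueError("pseudocount must be in [0, 1)")
    if background is None:
        background = BACKGROUND_COMPOSITION
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background must be a 20-vector summing to 1")
    idx = alignment if isinstance(alignment, np.ndarray) else alignment.to_indices()
    if weights is None:
        weights = np.ones(idx.shape[0])
    weights = np.asarray(weights, dtype=float)
    oh = _onehot(idx)
    raw = np.einsum("s,spa->pa", weights, oh) / weights.sum()
    fi = (1 - pseudocount) * raw + pseudocount * background
    flat = oh.reshape(idx.shape[0], -1)
    return WeightedFrequencies(weights, background, pseudocount, fi, flat)


# ---------------------------------------------------------------------------
# Conservation


@dataclass
class ConservationProfile:
    """Per-position relative entropy (nats) vs the background composition."""

    values: np.ndarray  # (p,)
    domain_means: dict[str, float] = field(default_factory=dict)

    def to_frame(self, refmap: ReferenceMap | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"position": np.arange(len(self.values)), "D": self.values})
        if refmap is not None:
            df["refnum"] = [refmap.col_to_resnum.get(i) for i in df["position"]]
        return df


def relative_entropy_profile(
    freqs: WeightedFrequencies | np.ndarray,
    background: np.ndarray | None = None,
    domains: dict[str, Sequence[int]] | None = None,
) -> ConservationProfile:
    """Kullback-Leibler conservation ``D_i = sum_a f_i^a ln(f_i^a / q_a)``.

    Zero-frequency terms contribute 0.  ``domains`` optionally maps a domain
    name to the column indices it spans; per-domain mean D is reported.
    """
    if isinstance(freqs, WeightedFrequencies):
        f = freqs.fi
        q = freqs.background if background is None else np.asarray(background)
    else:
        f = np.asarray(freqs, dtype=float)
        if background is None:
            raise ValueError("background required when passing a raw frequency array")
        q = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / q), 0.0)
    D = terms.sum(axis=1)
    means = {}
    if domains:
        for name, cols in domains.items():
            cols = np.asarray(list(cols), dtype=int)
            means[name] = float(D[cols].mean()) if len(cols) else float("nan")
    return ConservationProfile(D, means)


# ---------------------------------------------------------------------------
# Coupling matrix


def sca_matrix(
    alignment: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    freqs: WeightedFrequencies | None = None,
) -> np.ndarray:
    """Conservation-weighted coupling magnitudes, shape (p, p).

    ``Ct_ij = sqrt( sum_ab (phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b))^2 )`` —
    the Frobenius compression of the phi-weighted amino-acid covariance.
    """
    shape = (
        alignment.shape
        if isinstance(alignment, np.ndarray)
        else (alignment.n_seq, alignment.n_cols)
    )
    if shape[0] < 2:
        raise ValueError("need at least 2 sequences for covariance")
    if shape[1] < 2:
        raise ValueError("need at least 2 positions")
    if freqs is None:
        freqs = weighted_frequencies(alignment, weights, pseudocount, background)
    p = freqs.n_positions
    fij = freqs.pairwise()
    cov = fij - np.einsum("ia,jb->iajb", freqs.fi, freqs.fi)
    phi = freqs.phi
    weighted = np.einsum("ia,jb,iajb->iajb", phi, phi, cov)
    ct = np.sqrt(np.einsum("iajb,iajb->ij", weighted, weighted))
    # exact symmetry against floating-point asymmetry in einsum order
    return (ct + ct.T) / 2.0


def sca_matrix_bruteforce(
    alignment: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Literal double-loop evaluation of the coupling formula (oracle).

    Kept deliberately naive — per-pair frequency counting with explicit
    loops — as an independent check of :func:`sca_matrix` on small inputs.
    """
    if background is None:
        background = BACKGROUND_COMPOSITION
    if weights is None:
        weights = np.ones(alignment.n_seq)
    lam = pseudocount
    idx = alignment.to_indices()
    n, p = idx.shape
    W = np.sum(weights)
    fi = np.zeros((p, 20))
    for i in range(p):
        for a in range(20):
            raw = sum(weights[s] for s in range(n) if idx[s, i] == a) / W
            fi[i, a] = (1 - lam) * raw + lam * background[a]
    fc = np.clip(fi, 1e-12, 1 - 1e-12)
    phi = np.log(fc * (1 - background) / (background * (1 - fc)))
    ct = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            total = 0.0
            for a in range(20):
                for b in range(20):
                    raw = (
                        sum(
                            weights[s]
                            for s in range(n)
                            if idx[s, i] == a and idx[s, j] == b
                        )
                        / W
                    )
                    fij = (1 - lam) * raw + lam * background[a] * background[b]
                    c = fij - fi[i, a] * fi[j, b]
                    total += (phi[i, a] * phi[j, b] * c) ** 2
            ct[i, j] = np.sqrt(total)
    return ct


# ---------------------------------------------------------------------------
# Spectral significance


@dataclass
class SpectralModes:
    """Eigen-decomposition of the coupling matrix with a permutation null.

    ``k_significant`` counts actual eigenvalues above the stated percentile
    of the null distribution of maximum eigenvalues.
    """

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # (p, p), column k pairs with eigenvalues[k]
    null_max_eigenvalues: np.ndarray
    significance_threshold: float
    k_significant: int
    percentile: float


def _permuted_columns(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(idx)
    n = idx.shape[0]
    for j in range(idx.shape[1]):
        out[:, j] = idx[rng.permutation(n), j]
    return out


def spectral_modes(
    ct: np.ndarray,
    alignment: Alignment,
    weights: np.ndarray | None = None,
    n_null: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> SpectralModes:
    """Eigen-spectrum of ``ct`` with a column-permutation null.

    Each null replicate permutes every alignment column independently across
    rows (destroying inter-position correlation while preserving column
    composition), recomputes the coupling matrix with the *same* sequence
    weights, and records its maximum eigenvalue.  The significance line is
    the requested percentile of those maxima.
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    evals, evecs = np.linalg.eigh(ct)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.ones(alignment.n_seq)
    idx = alignment.to_indices()
    null_max = np.empty(n_null)
    for r in range(n_null):
        perm = _permuted_columns(idx, rng)
        ct_r = sca_matrix(perm, weights, pseudocount, background)
        null_max[r] = np.linalg.eigvalsh(ct_r).max()
    threshold = float(np.percentile(null_max, percentile))
    k = int((evals > threshold).sum())
    return SpectralModes(evals, evecs, null_max, threshold, k, percentile)


# ---------------------------------------------------------------------------
# ICA


@dataclass
class ICAResult:
    components: np.ndarray  # (p, k) rotated loading vectors
    rotation: np.ndarray  # (k, k) orthogonal matrix applied
    converged: bool
    n_iter: int


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, U = np.linalg.eigh(W @ W.T)
    return U @ np.diag(1.0 / np.sqrt(np.maximum(s, 1e-300))) @ U.T @ W


def ica_rotation(
    vectors: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> ICAResult:
    """Rotate orthonormal loading vectors toward independent components.

    Symmetric fixed-point iteration with the ``tanh`` non-Gaussianity
    contrast.  Because the input columns are orthonormal the data are already
    white (up to the uniform scale ``sqrt(p)``), so the learned unmixing
    matrix is exactly orthogonal and the spanned subspace is preserved.

    Components are sign-oriented so each one's largest-magnitude loading is
    positive, and ordered to match the input vectors (greedy maximal
    |correlation| assignment).  ``k = 1`` returns the input unchanged.
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2:
        raise ValueError("vectors must be a (p, k) array")
    p, k = V.shape
    if k == 1:
        comp = V.copy()
        rot = np.eye(1)
        j = np.argmax(np.abs(comp[:, 0]))
        if comp[j, 0] < 0:
            comp, rot = -comp, -rot
        return ICAResult(comp, rot, True, 0)

    X = V.T * np.sqrt(p)  # (k, p); X X^T = p I exactly
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((k, k)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WX = W @ X
        G = np.tanh(WX)
        g_prime_mean = (1.0 - G**2).mean(axis=1)
        W_new = (G @ X.T) / p - g_prime_mean[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not converge in {max_iter} iterations (delta={lim:.2e}); "
            "returning best iterate",
            RuntimeWarning,
        )
    comps = (W @ X).T / np.sqrt(p)  # (p, k), columns orthonormal

    # order components by greedy |corr| match to the input vectors
    corr = np.abs(V.T @ comps)  # (k_in, k_out)
    order = [-1] * k
    used: set[int] = set()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        order[i] = int(j)
        used.add(int(j))
        corr[i, :] = -1
        corr[:, j] = -1
    comps = comps[:, order]
    W = W[order, :]
    # sign orientation: largest-magnitude loading positive
    for c in range(k):
        j = np.argmax(np.abs(comps[:, c]))
        if comps[j, c] < 0:
            comps[:, c] = -comps[:, c]
            W[c, :] = -W[c, :]
    return ICAResult(comps, W, converged, it)


# ---------------------------------------------------------------------------
# Sectors


@dataclass
class Sector:
    label: str
    positions: tuple[int, ...]  # reference residue numbers
    loadings: dict[int, float]
    component: int

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SectorSet:
    sectors: list[Sector]
    cutoff_rule: str

    def __iter__(self):
        return iter(self.sectors)

    def __len__(self):
        return len(self.sectors)

    def __getitem__(self, label: str) -> Sector:
        for s in self.sectors:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sectors:
            for pos in s.positions:
                rows.append({"sector": s.label, "refnum": pos, "loading": s.loadings[pos]})
        return pd.DataFrame(rows, columns=["sector", "refnum", "loading"])


def extract_sectors(
    components: np.ndarray,
    refmap: ReferenceMap | None = None,
    n_sd: float = 2.0,
) -> SectorSet:
    """Threshold independent components into sectors.

    A position qualifies for a component when its loading exceeds that
    component's ``mean + n_sd * sd``; each qualifying position is assigned to
    the component on which its loading is maximal.  Positions are reported in
    reference numbering when ``refmap`` is given (column index + 1 otherwise).
    Empty sectors are retained with a warning.
    """
    comps = np.asarray(components, dtype=float)
    p, k = comps.shape
    thresholds = comps.mean(axis=0) + n_sd * comps.std(axis=0)
    qualifies = comps > thresholds[None, :]
    best = np.argmax(comps, axis=1)
    sectors = []
    for c in range(k):
        members = [i for i in range(p) if qualifies[i, c] and best[i] == c]
        if refmap is not None:
            nums = [refmap.col_to_resnum[i] for i in members]
        else:
            nums = [i + 1 for i in members]
        loadings = {n: float(comps[i, c]) for n, i in zip(nums, members)}
        if not members:
            warnings.warn(f"sector {c + 1} is empty under the mean+{n_sd}sd rule")
        sectors.append(Sector(f"sector_{c + 1}", tuple(nums), loadings, c))
    return SectorSet(sectors, f"loading > mean + {n_sd}*sd")


def sector_overlap(sector_a: Sector | Sequence[int], sector_b: Sector | Sequence[int]) -> float:
    """``|A intersect B| / |A|``; NaN (with a warning) for an empty A."""
    a = set(sector_a.positions if isinstance(sector_a, Sector) else sector_a)
    b = set(sector_b.positions if isinstance(sector_b, Sector) else sector_b)
    if not a:
        warnings.warn("sector overlap undefined for an empty first sector")
        return float("nan")
    return len(a & b) / len(a)


# ---------------------------------------------------------------------------
# Amino-acid-level statistics


@dataclass
class CooccurrenceTable:
    """Weighted 21x21 contingency table for a pair of positions.

    Index order is the 20 standard residues followed by the gap symbol.
    ``conditional()`` gives rows of P(a_j | a_i); ``mutual_information`` is in
    nats over the full 21x21 joint.
    """

    pos_i: int
    pos_j: int
    counts: pd.DataFrame  # 21x21, rows = residue at i, cols = residue at j
    mutual_information: float

    def joint(self) -> pd.DataFrame:
        return self.counts / self.counts.values.sum()

    def conditional(self) -> pd.DataFrame:
        """P(a_j | a_i); rows with zero marginal are NaN."""
        marg = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts.div(marg.replace(0.0, np.nan), axis=0)


def cooccurrence_table(
    alignment: Alignment,
    weights: np.ndarray | None = None,
    pos_i: int = 0,
    pos_j: int = 1,
) -> CooccurrenceTable:
    """Weighted co-occurrence of residues at two alignment columns."""
    for pos in (pos_i, pos_j):
        if not 0 <= pos < alignment.n_cols:
            raise IndexError(f"position {pos} out of range")
    if weights is None:
        weights = np.ones(alignment.n_seq)
    weights = np.asarray(weights, dtype=float)
    idx = alignment.to_indices()
    table = np.zeros((21, 21))
    np.add.at(table, (idx[:, pos_i], idx[:, pos_j]), weights)
    labels = list(AA_ALPHABET) + ["-"]
    counts = pd.DataFrame(table, index=labels, columns=labels)
    P = table / table.sum()
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(P > 0, P * np.log(P / np.outer(pi, pj)), 0.0)
    mi = max(float(terms.sum()), 0.0)
    return CooccurrenceTable(pos_i, pos_j, counts, mi)


def perturbation_profile(
    alignment: Alignment,
    weights: np.ndarray | None = None,
    condition: tuple[int, str] = (0, "A"),
    min_subset: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Amino-acid-level perturbation statistic.

    Restricting the alignment to sequences carrying residue ``aa`` at
    position ``pos_i`` shifts every other position's frequencies by
    ``Delta f_j^b``; the per-position statistic is the phi-weighted magnitude
    ``DD_j = sqrt( sum_b (phi_j^b Delta f_j^b)^2 )`` with phi from the full
    alignment.  ``min_subset`` is the minimum weighted subset size as a
    fraction of the total weight.
    """
    pos_i, aa = condition
    if not 0 <= pos_i < alignment.n_cols:
        raise IndexError(f"position {pos_i} out of range")
    if aa not in AA_INDEX:
        raise ValueError(f"unknown residue {aa!r}")
    if weights is None:
        weights = np.ones(alignment.n_seq)
    weights = np.asarray(weights, dtype=float)
    idx = alignment.to_indices()
    mask = idx[:, pos_i] == AA_INDEX[aa]
    subset_w = weights[mask].sum()
    if subset_w < min_subset * weights.sum():
        raise ValueError(
            f"subset for condition (pos {pos_i}, {aa}) has weight "
            f"{subset_w:.3g} < {min_subset:.3g} of total {weights.sum():.3g}"
        )
    full = weighted_frequencies(alignment, weights, pseudocount, background)
    sub = weighted_frequencies(
        alignment.select_rows(np.nonzero(mask)[0]),
        weights[mask],
        pseudocount,
        full.background,
    )
    delta = sub.fi - full.fi
    return np.sqrt(((full.phi * delta) ** 2).sum(axis=1))


# ---------------------------------------------------------------------------
# Model / results


class SCA:
    """Statistical coupling analysis model for one alignment.

    Parameters
    ----------
    alignment
        The (already assembled and truncated) alignment to analyze.
    refmap
        Optional column -> reference-residue-number map; sector positions are
        reported through it.
    neighbor_identity
        Identity level defining "neighbors" for sequence weighting.
    pseudocount, background
        Frequency regularization parameters.
    """

    def __init__(
        self,
        alignment: Alignment,
        refmap: ReferenceMap | None = None,
        neighbor_identity: float = 0.8,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray | None = None,
    ):
        if alignment.n_seq < 2:
            raise ValueError("SCA requires at least 2 sequences")
        self.alignment = alignment
        self.refmap = refmap
        self.neighbor_identity = neighbor_identity
        self.pseudocount = pseudocount
        self.background = (
            BACKGROUND_COMPOSITION if background is None else np.asarray(background)
        )

    @classmethod
    def from_file(cls, path, format="fasta", **kwargs) -> "SCA":
        from .alignment import read_alignment

        return cls(read_alignment(path, format), **kwargs)

    def fit(
        self,
        n_null: int = 100,
        percentile: float = 95.0,
        seed: int = 0,
        n_components: int | None = None,
        include_first_mode: bool = True,
        sector_sd: float = 2.0,
        ica_tol: float = 1e-8,
        ica_max_iter: int = 1000,
    ) -> "SCAResults":
        """Run the full SCA pipeline and return the results object.

        ``n_components`` overrides the spectral significance count; by
        default the number of independent components equals ``k_significant``
        (at least 1).  ``include_first_mode=False`` drops the top
        ("global conservation") eigenmode before ICA.
        """
        weights = sequence_weights(self.alignment, self.neighbor_identity)
        freqs = weighted_frequencies(
            self.alignment, weights, self.pseudocount, self.background
        )
        conservation = relative_entropy_profile(freqs)
        ct = sca_matrix(self.alignment, weights, freqs=freqs)
        modes = spectral_modes(
            ct,
            self.alignment,
            weights,
            n_null=n_null,
            seed=seed,
            percentile=percentile,
            pseudocount=self.pseudocount,
            background=self.background,
        )
        k = n_components if n_components is not None else max(modes.k_significant, 1)
        first = 0 if include_first_mode else 1
        k_eff = max(k - first, 1) if not include_first_mode else max(k, 1)
        top = modes.eigenvectors[:, first : first + k_eff]
        ica = ica_rotation(top, tol=ica_tol, max_iter=ica_max_iter, seed=seed)
        sectors = extract_sectors(ica.components, self.refmap, n_sd=sector_sd)
        return SCAResults(
            model=self,
            weights=weights,
            freqs=freqs,
            conservation=conservation,
            coupling_matrix=ct,
            modes=modes,
            ica=ica,
            sectors=sectors,
            seed=seed,
        )


@dataclass
class SCAResults:
    """Fitted SCA results: matrices, spectra, components and sectors."""

    model: SCA
    weights: np.ndarray
    freqs: WeightedFrequencies
    conservation: ConservationProfile
    coupling_matrix: np.ndarray
    modes: SpectralModes
    ica: ICAResult
    sectors: SectorSet
    seed: int

    @property
    def k_significant(self) -> int:
        return self.modes.k_significant

    def eigenvalue_table(self) -> pd.DataFrame:
        ev = self.modes.eigenvalues
        return pd.DataFrame(
            {
                "mode": np.arange(1, len(ev) + 1),
                "eigenvalue": ev,
                "null_threshold": self.modes.significance_threshold,
                "significant": ev > self.modes.significance_threshold,
            }
        )

    def summary(self) -> str:
        a = self.model.alignment
        lines = [
            "Statistical Coupling Analysis",
            "=" * 46,
            f"Sequences:            {a.n_seq}",
            f"Effective sequences:  {self.freqs.effective_sequences:.1f}",
            f"Positions:            {a.n_cols}",
            f"Pseudocount:          {self.freqs.pseudocount}",
            f"Null replicates:      {len(self.modes.null_max_eigenvalues)}",
            f"Significance line:    {self.modes.significance_threshold:.4f} "
            f"({self.modes.percentile:.0f}th pct of null max eigenvalue)",
            f"Significant modes:    {self.modes.k_significant}",
            f"ICA converged:        {self.ica.converged} ({self.ica.n_iter} iterations)",
            f"Sectors ({self.sectors.cutoff_rule}):",
        ]
        for s in self.sectors:
            pos = ", ".join(map(str, s.positions[:8]))
            more = f" ... (+{len(s) - 8})" if len(s) > 8 else ""
            lines.append(f"  {s.label}: {len(s)} positions [{pos}{more}]")
        return "\n".join(lines)
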