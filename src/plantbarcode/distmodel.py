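"""Pairwise evolutionary distances between aligned nucleotide sequences.

Implements p-distance, Jukes–Cantor, Kimura 2-parameter and Tamura–Nei
(TN93) distances from per-pair site-pattern counts, and a composite-
likelihood TN93 variant in which the base frequencies and the two
transition/transversion rate ratios are estimated once over all pairs
(the sum of per-pair multinomial log-likelihoods) and then applied to
every pair. Gap/missing sites are handled by pairwise or complete
deletion; saturated pairs yield UNDEFINED (NaN, explicitly flagged)
rather than a silently capped value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .seqio import SeqRecordSet

UNDEFINED = float("nan")

#: nucleotide encoding: A=0, C=1, G=2, T=3; everything else (gap, N) = -1
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate("ACGT"):
    _LUT[ord(_ch)] = _i
    _LUT[ord(_ch.lower())] = _i

_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SubstitutionCounts:
    """Site-pattern counts for one sequence pair.

    identical + ts_purine + ts_pyrimidine + transversions = n_sites.
    ``freqs`` are the empirical A,C,G,T frequencies of the two sequences
    over the compared sites (they sum to 1 when n_sites > 0).
    """

    n_sites: int
    identical: int
    ts_purine: int
    ts_pyrimidine: int
    transversions: int
    freqs: np.ndarray

    @property
    def transitions(self) -> int:
        return self.ts_purine + self.ts_pyrimidine


def count_site_patterns(
    seq_a: str, seq_b: str, deletion: str = "pairwise", mask: np.ndarray | None = None
) -> SubstitutionCounts:
    """Count identical sites, the two transition classes and transversions.

    Sites where either sequence carries a gap or N are excluded (pairwise
    deletion). Under complete deletion over a whole alignment, pass the
    shared column ``mask`` computed once (True = keep); for a lone pair the
    two modes coincide. Zero comparable sites is signalled by
    ``n_sites == 0`` and propagates as an UNDEFINED distance.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a >= 0) & (b >= 0)
    if mask is not None:
        valid &= mask
    a, b = a[valid], b[valid]
    n = a.size
    if n == 0:
        return SubstitutionCounts(0, 0, 0, 0, 0, np.full(4, np.nan))
    ident = int((a == b).sum())
    ts_pur = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    ts_pyr = int((((a == 1) & (b == 3)) | ((a == 3) & (b == 1))).sum())
    tv = n - ident - ts_pur - ts_pyr
    freqs = (np.bincount(a, minlength=4) + np.bincount(b, minlength=4)) / (2 * n)
    return SubstitutionCounts(n, ident, ts_pur, ts_pyr, tv, freqs)


def p_distance(counts: SubstitutionCounts) -> float:
    if counts.n_sites == 0:
        return UNDEFINED
    return (counts.n_sites - counts.identical) / counts.n_sites


def jc_distance(counts: SubstitutionCounts) -> float:
    """Jukes–Cantor distance, d = -(3/4) ln(1 - (4/3) p); saturates at p >= 0.75."""
    p = p_distance(counts)
    if is_undefined(p) or p >= 0.75:
        return UNDEFINED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p_distance(counts: SubstitutionCounts) -> float:
    """Kimura 2-parameter distance from transition (P) and transversion (Q) proportions."""
    if counts.n_sites == 0:
        return UNDEFINED
    P = counts.transitions / counts.n_sites
    Q = counts.transversions / counts.n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def tn93_distance(counts: SubstitutionCounts, freqs: np.ndarray | None = None) -> float:
    """Tamura–Nei (1993) distance from the pair's own counts.

    Uses the pair's empirical base frequencies unless ``freqs`` overrides
    them (the composite-likelihood matrix passes pooled frequencies when
    a per-pair fallback is wanted). Non-positive logarithm arguments
    (saturation) yield UNDEFINED.
    """
    if counts.n_sites == 0:
        return UNDEFINED
    pi = counts.freqs if freqs is None else np.asarray(freqs, dtype=float)
    pA, pC, pG, pT = pi
    pR, pY = pA + pG, pC + pT
    P1 = counts.ts_purine / counts.n_sites
    P2 = counts.ts_pyrimidine / counts.n_sites
    Q = counts.transversions / counts.n_sites
    if pR <= 0 or pY <= 0:
        return UNDEFINED
    k1 = 2.0 * pA * pG / pR
    k2 = 2.0 * pT * pC / pY
    k3 = 2.0 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)
    d = 0.0
    for k, w in (
        (k1, 1.0 - (P1 / k1 if k1 > 0 else (math.inf if P1 > 0 else 0.0)) - Q / (2.0 * pR)),
        (k2, 1.0 - (P2 / k2 if k2 > 0 else (math.inf if P2 > 0 else 0.0)) - Q / (2.0 * pY)),
        (k3, 1.0 - Q / (2.0 * pR * pY)),
    ):
        if k > 0:
            if w <= 0 or not math.isfinite(w):
                return UNDEFINED
            d += -k * math.log(w)
    return d


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with model provenance.

    Entries are substitutions/site; UNDEFINED (saturated or incomparable)
    entries are NaN and exposed through :meth:`is_defined` — they are never
    silent: consumers such as NJ refuse to run on them.
    """

    labels: list[str]
    values: np.ndarray
    model: str
    deletion: str = "pairwise"
    n_sites_used: np.ndarray | None = None
    params: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T]
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, 1)
        return int(np.isnan(self.values[iu]).sum())

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.8f")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                name = label.replace(" ", "_")
                fh.write(name + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")

    def capped(self, cap: float) -> "DistanceMatrix":
        """Replace UNDEFINED entries with a fixed cap (opt-in; distorts gap statistics)."""
        values = self.values.copy()
        values[np.isnan(values)] = cap
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(self.labels, values, self.model, self.deletion, self.n_sites_used, self.params)


_PAIR_FUNCS: dict[str, Callable[[SubstitutionCounts], float]] = {
    "p": p_distance,
    "JC": jc_distance,
    "K2P": k2p_distance,
    "TN93": tn93_distance,
}


def _complete_deletion_mask(seqs: SeqRecordSet) -> np.ndarray:
    codes = np.stack([encode(s) for s in seqs.sequences])
    return (codes >= 0).all(axis=0)


def distance_matrix(seqs: SeqRecordSet, model: str = "p", deletion: str = "pairwise") -> DistanceMatrix:
    """Pairwise distance matrix under one of the per-pair models (p, JC, K2P, TN93).

    For the pooled composite-likelihood model use :func:`mcl_distance_matrix`.
    """
    if model == "MCL":
        return mcl_distance_matrix(seqs, deletion=deletion)
    if model not in _PAIR_FUNCS:
        raise ValueError(f"unknown model {model!r}")
    if not seqs.aligned:
        raise ValueError("sequences must be aligned")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    fn = _PAIR_FUNCS[model]
    n = len(seqs)
    mask = _complete_deletion_mask(seqs) if deletion == "complete" else None
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int(mask.sum()) if mask is not None else len(seqs.sequences[i])
        for j in range(i + 1, n):
            c = count_site_patterns(seqs.sequences[i], seqs.sequences[j], mask=mask)
            values[i, j] = values[j, i] = fn(c)
            sites[i, j] = sites[j, i] = c.n_sites
    return DistanceMatrix(list(seqs.ids), values, model, deletion, sites)


# ---------------------------------------------------------------------------
# TN93 model machinery (shared by the composite-likelihood fit and the
# sequence simulator)


def tn93_rate_matrix(freqs: Sequence[float], kappa1: float, kappa2: float) -> np.ndarray:
    """TN93 instantaneous rate matrix, scaled to one expected substitution per unit time.

    kappa1 and kappa2 are the purine (A<->G) and pyrimidine (C<->T)
    transition/transversion rate ratios.
    """
    pi = np.asarray(freqs, dtype=float)
    pA, pC, pG, pT = pi
    pR, pY = pA + pG, pC + pT
    beta = 1.0 / (2.0 * (pA * pG * kappa1 + pC * pT * kappa2 + pR * pY))
    rate = np.full((4, 4), beta)
    rate[0, 2] = rate[2, 0] = kappa1 * beta
    rate[1, 3] = rate[3, 1] = kappa2 * beta
    Q = rate * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class _TN93Spectral:
    """Spectral decomposition of a TN93 rate matrix.

    Provides vectorised transition matrices P(t) and the expected
    proportions of the three observable difference classes at divergence t
    (total substitutions/site across both branches of a pair).
    """

    def __init__(self, freqs: Sequence[float], kappa1: float, kappa2: float):
        pi = np.clip(np.asarray(freqs, dtype=float), 1e-8, None)
        pi = pi / pi.sum()
        self.pi = pi
        Q = tn93_rate_matrix(pi, kappa1, kappa2)
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        S = 0.5 * (S + S.T)  # reversibility => symmetric up to round-off
        w, V = np.linalg.eigh(S)
        self.w, self.V, self.sq = w, V, sq
        # F_ij(t) = pi_i P_ij(t) = sqrt(pi_i pi_j) sum_k V_ik V_jk e^{w_k t}
        def coef(i: int, j: int) -> np.ndarray:
            return sq[i] * sq[j] * V[i] * V[j]

        self.c_p1 = 2.0 * coef(0, 2)                       # A<->G differences
        self.c_p2 = 2.0 * coef(1, 3)                       # C<->T differences
        self.c_q = 2.0 * (coef(0, 1) + coef(0, 3) + coef(2, 1) + coef(2, 3))

    def transition_matrix(self, t: float) -> np.ndarray:
        E = self.V * np.exp(self.w * t)[None, :]
        P = (E @ self.V.T) / self.sq[:, None] * self.sq[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def pattern_props(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        E = np.exp(np.outer(t, self.w))
        return E @ self.c_p1, E @ self.c_p2, E @ self.c_q


def tn93_transition_matrix(freqs: Sequence[float], kappa1: float, kappa2: float, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled TN93 rate matrix (t in expected subs/site)."""
    return _TN93Spectral(freqs, kappa1, kappa2).transition_matrix(t)


_T_MAX = 15.0
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _pair_loglik(spec: _TN93Spectral, t: np.ndarray, n1, n2, nq, n0) -> np.ndarray:
    P1, P2, Qv = spec.pattern_props(t)
    P1 = np.clip(P1, 1e-300, 1.0)
    P2 = np.clip(P2, 1e-300, 1.0)
    Qv = np.clip(Qv, 1e-300, 1.0)
    P0 = np.clip(1.0 - P1 - P2 - Qv, 1e-300, 1.0)
    return n1 * np.log(P1) + n2 * np.log(P2) + nq * np.log(Qv) + n0 * np.log(P0)


def _profile_distances(
    spec: _TN93Spectral, n1, n2, nq, n0, iters: int = 60
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair ML divergence under fixed model parameters (vectorised golden section)."""
    m = len(n1)
    a = np.zeros(m)
    b = np.full(m, _T_MAX)
    for _ in range(iters):
        h = b - a
        x1 = a + (1.0 - _GOLDEN) * h
        x2 = a + _GOLDEN * h
        f1 = _pair_loglik(spec, x1, n1, n2, nq, n0)
        f2 = _pair_loglik(spec, x2, n1, n2, nq, n0)
        left = f1 >= f2  # maximum lies in [a, x2]
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
    t_hat = 0.5 * (a + b)
    no_diff = (n1 + n2 + nq) == 0
    t_hat = np.where(no_diff, 0.0, t_hat)
    ll = _pair_loglik(spec, t_hat, n1, n2, nq, n0)
    ll = np.where(no_diff, 0.0 * ll, ll)
    # a pair whose likelihood keeps increasing to the bound is saturated
    saturated = (~no_diff) & (t_hat > _T_MAX - 0.1)
    return t_hat, np.where(saturated, -np.inf, ll), saturated


def mcl_distance_matrix(seqs: SeqRecordSet, deletion: str = "pairwise") -> DistanceMatrix:
    """Composite-likelihood TN93 distance matrix (pooled model parameters).

    Base frequencies are pooled over all sequences; the two
    transition/transversion rate ratios (kappa1, kappa2) maximise the sum
    over all pairs of the multinomial log-likelihood of the observed site
    patterns, profiling out each pair's divergence. Per-pair distances are
    then the ML divergences under the pooled parameters. Rates are uniform
    across sites. Deterministic: three fixed optimiser starts, ties broken
    towards the lowest kappa1.
    """
    if not seqs.aligned:
        raise ValueError("sequences must be aligned")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(seqs)
    mask = _complete_deletion_mask(seqs) if deletion == "complete" else None
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = [
        count_site_patterns(seqs.sequences[i], seqs.sequences[j], mask=mask) for i, j in pairs
    ]
    if any(c.n_sites == 0 for c in counts):
        bad = next((i, j) for (i, j), c in zip(pairs, counts) if c.n_sites == 0)
        labels = seqs.ids
        raise ValueError(
            f"no comparable sites between {labels[bad[0]]!r} and {labels[bad[1]]!r}"
        )
    n1 = np.array([c.ts_purine for c in counts], dtype=float)
    n2 = np.array([c.ts_pyrimidine for c in counts], dtype=float)
    nq = np.array([c.transversions for c in counts], dtype=float)
    n0 = np.array([c.identical for c in counts], dtype=float)
    n_sites = np.array([c.n_sites for c in counts], dtype=int)

    # pooled base frequencies over all used sites of all sequences
    codes = np.stack([encode(s) for s in seqs.sequences])
    if mask is not None:
        codes = codes[:, mask]
    flat = codes[codes >= 0]
    freqs = np.bincount(flat, minlength=4).astype(float)
    freqs = np.clip(freqs / max(flat.size, 1), 1e-8, None)
    freqs = freqs / freqs.sum()

    def neg_cll(x: np.ndarray) -> float:
        spec = _TN93Spectral(freqs, math.exp(x[0]), math.exp(x[1]))
        _, ll, _ = _profile_distances(spec, n1, n2, nq, n0)
        finite = np.isfinite(ll)
        if not finite.any():
            return 1e12
        return -float(ll[finite].sum()) + 1e6 * float((~finite).sum())

    bounds = [(math.log(0.02), math.log(500.0))] * 2
    best = None
    for start in (0.5, 2.0, 8.0):
        x0 = np.log([start, start])
        res = minimize(neg_cll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-8, "gtol": 1e-8})
        cand = (res.fun, math.exp(res.x[0]), math.exp(res.x[1]))
        if best is None:
            best = cand
        else:
            # tie (relative 1e-9) resolved towards the lowest kappa1
            if cand[0] < best[0] * (1 - 1e-9) - 1e-12:
                best = cand
            elif abs(cand[0] - best[0]) <= 1e-9 * max(1.0, abs(best[0])) and cand[1] < best[1]:
                best = cand
    _, kappa1, kappa2 = best
    spec = _TN93Spectral(freqs, kappa1, kappa2)
    t_hat, _, saturated = _profile_distances(spec, n1, n2, nq, n0, iters=90)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for (i, j), t, sat, ns in zip(pairs, t_hat, saturated, n_sites):
        values[i, j] = values[j, i] = UNDEFINED if sat else float(t)
        sites[i, j] = sites[j, i] = ns
    for i in range(n):
        sites[i, i] = int(mask.sum()) if mask is not None else len(seqs.sequences[i])
    return DistanceMatrix(
        list(seqs.ids),
        values,
        "MCL",
        deletion,
        sites,
        params={"kappa1": float(kappa1), "kappa2": float(kappa2), "freqs": freqs.tolist()},
    )
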