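"""Codon-level evolutionary machinery.

The substitution model is the Goldman–Yang style 61-state Markov process:
an instantaneous change between sense codons ``i`` and ``j`` differing at a
single nucleotide has rate ``pi_j`` times ``kappa`` for transitions and
times ``omega`` when the change is nonsynonymous. The matrix is scaled to
one expected substitution per codon per unit branch length. Likelihoods are
computed with Felsenstein pruning over compressed site patterns; the matrix
exponential uses the symmetric eigendecomposition available for reversible
chains.

Model fitting
-------------
* ``m0_fit`` maximises the one-ratio likelihood jointly over kappa, omega
  and all branch lengths. Its branch lengths feed both the comparative
  regressions and the site models.
* ``site_model_fit`` fits the standard site-class mixtures (M1a, M2a, M7,
  M8, M8a). Branch lengths are held at the M0 estimates times a single free
  scale factor rather than re-optimised per model; the nesting relations
  between the mixtures are unaffected. Each fit is multi-started (M0-based,
  perturbed, near-neutral, plus any caller-supplied warm starts).
* ``eb_sites`` computes naive empirical-Bayes posteriors for the
  positive-selection class by plugging in the maximum-likelihood estimates.

Branch rates use a counting estimator: per-nucleotide Fitch ancestral
reconstruction followed by Nei–Gojobori pathway counting per branch with a
Jukes–Cantor correction. Lineage omega for a tip is the ratio of dN and dS
sums along the root-to-tip path, which weights every lineage by the same
time span from the common ancestor.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    ModelMismatchError,
    OptimizationOrderError,
    StopCodonError,
)
from .io_formats import GappedAlignment, Phylogeny

logger = logging.getLogger("phyloindel")

NUCLEOTIDES = "TCAG"
STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))
SENSE_CODONS = tuple(
    sorted(c for c in standard_dna_table.forward_table)
)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


def _pair_tables():
    """Index arrays for all single-nucleotide sense-codon pairs."""
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(ci[k], cj[k]))
            syn.append(AMINO_ACID[ci] == AMINO_ACID[cj])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _pair_tables()


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-free in-frame codon matrix with provenance back to the alignment.

    ``codes[t, s]`` is the sense-codon index of taxon ``t`` at codon site
    ``s``; ``site_columns[s]`` is the 1-based alignment column of the site's
    first nucleotide, so flagged sites can be reported in both coordinate
    systems.
    """

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_codons) int
    site_columns: list[int]
    reference: str | None = None

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    def codon(self, taxon: str, site: int) -> str:
        return SENSE_CODONS[self.codes[self.taxa.index(taxon), site]]

    def residue(self, taxon: str, site: int) -> str:
        return AMINO_ACID[self.codon(taxon, site)]

    def protein(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(AMINO_ACID[SENSE_CODONS[c]] for c in row)


def build_codon_alignment(
    aln: GappedAlignment, reference: str | None = None
) -> CodonAlignment:
    """Drop every codon column containing a gap (or N) in any taxon.

    Raises :class:`StopCodonError` on an internal stop codon, naming the
    taxon and the 1-based codon site.
    """
    if aln.n_columns % 3 != 0:
        raise StopCodonError(
            f"alignment length {aln.n_columns} is not a multiple of 3"
        )
    taxa = aln.ids
    kept_codes: list[list[int]] = []
    site_columns: list[int] = []
    n_codon_cols = aln.n_columns // 3
    seqs = [r.seq for r in aln.records]
    for s in range(n_codon_cols):
        triplets = [seq[3 * s : 3 * s + 3] for seq in seqs]
        if any(("-" in t) or ("N" in t) for t in triplets):
            continue
        for taxon, t in zip(taxa, triplets):
            if t in STOP_CODONS:
                raise StopCodonError(
                    f"internal stop codon {t} in {taxon} at codon site {s + 1}"
                )
        kept_codes.append([CODON_INDEX[t] for t in triplets])
        site_columns.append(3 * s + 1)
    codes = (
        np.array(kept_codes, dtype=int).T
        if kept_codes
        else np.zeros((len(taxa), 0), dtype=int)
    )
    return CodonAlignment(taxa, codes, site_columns, reference=reference)


def f3x4_frequencies(caln: CodonAlignment) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific nucleotide use."""
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for t in range(caln.n_taxa):
        for s in range(caln.n_codons):
            codon = SENSE_CODONS[caln.codes[t, s]]
            for pos in range(3):
                counts[pos, nuc_idx[codon[pos]]] += 1
    counts += 0.5  # guard against unobserved nucleotides
    fracs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            fracs[0, nuc_idx[c[0]]] * fracs[1, nuc_idx[c[1]]] * fracs[2, nuc_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def f1x4_frequencies(caln: CodonAlignment) -> np.ndarray:
    counts = np.zeros(4)
    nuc_idx = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for t in range(caln.n_taxa):
        for s in range(caln.n_codons):
            for ch in SENSE_CODONS[caln.codes[t, s]]:
                counts[nuc_idx[ch]] += 1
    counts += 0.5
    frac = counts / counts.sum()
    pi = np.array(
        [frac[nuc_idx[c[0]]] * frac[nuc_idx[c[1]]] * frac[nuc_idx[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def f61_frequencies(caln: CodonAlignment) -> np.ndarray:
    counts = np.bincount(caln.codes.ravel(), minlength=N_SENSE).astype(float)
    counts += 0.5
    return counts / counts.sum()


def uniform_frequencies(_caln=None) -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


FREQUENCY_MODELS = {
    "F3x4": f3x4_frequencies,
    "F1x4": f1x4_frequencies,
    "F61": f61_frequencies,
    "uniform": uniform_frequencies,
}


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def codon_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, *, scale: bool = True
) -> np.ndarray:
    """GY-style instantaneous rate matrix over the 61 sense codons."""
    Q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[_PAIR_J].copy()
    rates[_PAIR_TS] *= kappa
    rates[~_PAIR_SYN] *= omega
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -(pi * np.diag(Q)).sum()
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def rate_matrix_mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    Q = codon_rate_matrix(kappa, omega, pi, scale=False)
    return -(pi * np.diag(Q)).sum()


class _Eigen:
    """Spectral form of a reversible rate matrix for cheap P(t)."""

    __slots__ = ("w", "A", "B")

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(np.maximum(pi, 1e-12))
        S = Q * sq[:, None] / sq[None, :]
        S = (S + S.T) / 2.0
        w, U = np.linalg.eigh(S)
        self.w = w
        self.A = U / sq[:, None]
        self.B = U.T * sq[None, :]

    def transition(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.w * t)) @ self.B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Pruning likelihood engine
# ---------------------------------------------------------------------------

class CodonLikelihood:
    """Felsenstein-pruning likelihood for (mixtures of) codon models on a
    fixed rooted topology, with site-pattern compression."""

    def __init__(
        self, caln: CodonAlignment, tree: Phylogeny, pi: np.ndarray | None = None
    ):
        if caln.n_codons == 0:
            raise StopCodonError("codon alignment has no sites")
        self.caln = caln
        self.tree = tree
        self.pi = pi if pi is not None else f3x4_frequencies(caln)
        tip_order = {t: i for i, t in enumerate(caln.taxa)}
        missing = [t for t in tree.tip_labels() if t not in tip_order]
        if missing:
            raise KeyError(f"tree tips missing from alignment: {missing}")
        patterns, inverse, counts = np.unique(
            caln.codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_taxa, n_patterns)
        self.pattern_of_site = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        # flattened postorder schedule
        self.edges = [n.name for n in tree.edges()]
        self.edge_index = {name: i for i, name in enumerate(self.edges)}
        self._postorder = [n for n in tree.postorder() if not n.is_tip]
        self._tip_row = {
            t: self.patterns[tip_order[t]] for t in tree.tip_labels()
        }
        self._eigen_cache: dict[tuple[float, float], _Eigen] = {}

    def _eigen(self, kappa: float, omega: float) -> _Eigen:
        key = (float(kappa), float(omega))
        eig = self._eigen_cache.get(key)
        if eig is None:
            Q = codon_rate_matrix(kappa, omega, self.pi, scale=False)
            eig = _Eigen(Q, self.pi)
            if len(self._eigen_cache) > 256:
                self._eigen_cache.clear()
            self._eigen_cache[key] = eig
        return eig

    def pattern_likelihoods(
        self, kappa: float, omega: float, branch_lengths: np.ndarray, rate: float = 1.0
    ) -> np.ndarray:
        """P(pattern) under a single-class model; branch lengths are expected
        substitutions per codon, divided by the mean rate of the unscaled Q."""
        eig = self._eigen(kappa, omega)
        mean_rate = rate
        partial: dict[str, np.ndarray] = {}
        for node in self._postorder:
            acc = np.ones((self.n_patterns, N_SENSE))
            for child in node.children:
                t = branch_lengths[self.edge_index[child.name]] / mean_rate
                P = eig.transition(t)
                if child.is_tip:
                    acc *= P[:, self._tip_row[child.name]].T
                else:
                    acc *= partial[child.name] @ P.T
            partial[node.name] = acc
        root = partial[self.tree.root.name]
        return root @ self.pi

    def loglik_single(
        self, kappa: float, omega: float, branch_lengths: np.ndarray
    ) -> float:
        rate = rate_matrix_mean_rate(kappa, omega, self.pi)
        L = self.pattern_likelihoods(kappa, omega, branch_lengths, rate)
        if np.any(L <= 0):
            return -np.inf
        return float(self.weights @ np.log(L))

    def class_pattern_likelihoods(
        self,
        kappa: float,
        classes: list[tuple[float, float]],
        branch_lengths: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern likelihood for each (proportion, omega) class.

        The mixture is normalised so that the proportion-weighted mean rate
        is one expected substitution per codon, matching how the branch
        lengths are interpreted.
        """
        props = np.array([p for p, _ in classes])
        omegas = [w for _, w in classes]
        rates = np.array([rate_matrix_mean_rate(kappa, w, self.pi) for w in omegas])
        mean_rate = float(props @ rates)
        out = np.empty((len(classes), self.n_patterns))
        for k, w in enumerate(omegas):
            out[k] = self.pattern_likelihoods(kappa, w, branch_lengths, mean_rate)
        return out

    def loglik_mixture(
        self,
        kappa: float,
        classes: list[tuple[float, float]],
        branch_lengths: np.ndarray,
    ) -> float:
        per_class = self.class_pattern_likelihoods(kappa, classes, branch_lengths)
        props = np.array([p for p, _ in classes])
        L = props @ per_class
        if np.any(L <= 0):
            return -np.inf
        return float(self.weights @ np.log(L))


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

SITE_MODELS = ("M1a", "M2a", "M7", "M8", "M8a")


@dataclass
class CodonModelFit:
    """Maximum-likelihood fit of one codon model."""

    model: str
    lnL: float
    kappa: float
    params: dict[str, float]
    branch_lengths: dict[str, float]
    classes: list[tuple[float, float]]  # (proportion, omega) per site class
    converged: bool
    n_codons: int
    frequencies: str = "F3x4"
    notes: str = ""
    site_class_posteriors: np.ndarray | None = field(default=None, repr=False)
    site_columns: list[int] = field(default_factory=list, repr=False)
    reference_protein: str | None = field(default=None, repr=False)

    @property
    def positive_class_index(self) -> int | None:
        for k, (_, w) in enumerate(self.classes):
            if w > 1.0 + 1e-9:
                return k
        return None

    def tree_length(self) -> float:
        return sum(self.branch_lengths.values())


def _finish_fit(engine, model, lnL, kappa, params, classes, bl, converged, notes=""):
    caln = engine.caln
    per_class = engine.class_pattern_likelihoods(kappa, classes, bl)
    props = np.array([p for p, _ in classes])
    mix = props @ per_class
    post = (props[:, None] * per_class) / np.where(mix > 0, mix, 1.0)
    site_post = post[:, engine.pattern_of_site].T  # (n_sites, K)
    ref = caln.reference if caln.reference in caln.taxa else caln.taxa[0]
    return CodonModelFit(
        model=model,
        lnL=lnL,
        kappa=kappa,
        params=params,
        branch_lengths={e: float(bl[i]) for i, e in enumerate(engine.edges)},
        classes=classes,
        converged=converged,
        n_codons=caln.n_codons,
        notes=notes,
        site_class_posteriors=site_post,
        site_columns=list(caln.site_columns),
        reference_protein=caln.protein(ref),
    )


def m0_fit(
    caln: CodonAlignment,
    tree: Phylogeny,
    *,
    frequencies: str = "F3x4",
    kappa0: float = 2.0,
    omega0: float = 0.4,
    t0: float = 0.1,
    maxiter: int = 500,
) -> CodonModelFit:
    """One-ratio model: joint ML over kappa, omega and all branch lengths.

    Branch lengths are in expected substitutions per codon. Raises
    :class:`ConvergenceError` if the optimiser makes no progress.
    """
    pi = FREQUENCY_MODELS[frequencies](caln)
    engine = CodonLikelihood(caln, tree, pi)
    n_edges = len(engine.edges)

    def unpack(x):
        return np.exp(x[:n_edges]), math.exp(x[n_edges]), math.exp(x[n_edges + 1])

    def negloglik(x):
        bl, kappa, omega = unpack(x)
        return -engine.loglik_single(kappa, omega, bl)

    x0 = np.concatenate(
        [np.log(np.full(n_edges, t0)), [math.log(kappa0), math.log(omega0)]]
    )
    bounds = (
        [(math.log(1e-7), math.log(30.0))] * n_edges
        + [(math.log(0.05), math.log(60.0)), (math.log(1e-5), math.log(40.0))]
    )
    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("M0 optimisation diverged", last_iterate=res.x)
    bl, kappa, omega = unpack(res.x)
    return _finish_fit(
        engine,
        "M0",
        -float(res.fun),
        kappa,
        {"omega": float(omega)},
        [(1.0, float(omega))],
        bl,
        bool(res.success),
    )


def _beta_category_omegas(p: float, q: float, k: int) -> np.ndarray:
    """Median omega of K equal-probability beta bins (discretised beta)."""
    quantiles = (np.arange(k) + 0.5) / k
    return stats.beta.ppf(quantiles, p, q)


class _MixtureSpec:
    """Parameter packing for one site-class model."""

    def __init__(self, model: str, n_beta: int):
        self.model = model
        self.n_beta = n_beta
        if model == "M1a":
            self.names = ["p0", "omega0"]
        elif model == "M2a":
            self.names = ["p0", "p1_rel", "omega0", "omega2"]
        elif model == "M7":
            self.names = ["p", "q"]
        elif model == "M8":
            self.names = ["p0", "p", "q", "omega_s"]
        elif model == "M8a":
            self.names = ["p0", "p", "q"]
        else:
            raise ModelMismatchError(f"unknown site model {model!r}")
        # every model also carries kappa and a branch-length scale
        self.bounds = {
            "p0": (1e-6, 1 - 1e-6),
            "p1_rel": (1e-6, 1 - 1e-6),
            "omega0": (1e-6, 1.0),
            "omega2": (1.0, 40.0),
            "omega_s": (1.0, 40.0),
            "p": (0.005, 100.0),
            "q": (0.005, 100.0),
            "kappa": (0.05, 60.0),
            "scale": (0.05, 20.0),
        }

    def classes(self, params: dict[str, float]) -> list[tuple[float, float]]:
        m = self.model
        if m == "M1a":
            p0 = params["p0"]
            return [(p0, params["omega0"]), (1 - p0, 1.0)]
        if m == "M2a":
            p0 = params["p0"]
            p1 = (1 - p0) * params["p1_rel"]
            p2 = 1 - p0 - p1
            return [(p0, params["omega0"]), (p1, 1.0), (p2, params["omega2"])]
        betas = _beta_category_omegas(params["p"], params["q"], self.n_beta)
        if m == "M7":
            w = 1.0 / self.n_beta
            return [(w, float(b)) for b in betas]
        p0 = params["p0"]
        w = p0 / self.n_beta
        cls = [(w, float(b)) for b in betas]
        omega_s = 1.0 if m == "M8a" else params["omega_s"]
        cls.append((1 - p0, float(omega_s)))
        return cls


def _default_starts(spec: _MixtureSpec, m0: CodonModelFit | None, rng) -> list[dict]:
    w0 = min(max(m0.params["omega"] if m0 else 0.3, 0.02), 0.9)
    m = spec.model
    starts = []
    if m == "M1a":
        starts = [
            {"p0": 0.6, "omega0": w0},
            {"p0": float(rng.uniform(0.2, 0.9)), "omega0": float(rng.uniform(0.01, 0.9))},
            {"p0": 0.9, "omega0": 0.05},
        ]
    elif m == "M2a":
        starts = [
            {"p0": 0.5, "p1_rel": 0.6, "omega0": w0, "omega2": 3.0},
            {
                "p0": float(rng.uniform(0.2, 0.8)),
                "p1_rel": float(rng.uniform(0.2, 0.8)),
                "omega0": float(rng.uniform(0.01, 0.9)),
                "omega2": float(rng.uniform(1.2, 8.0)),
            },
            {"p0": 0.85, "p1_rel": 0.9, "omega0": 0.05, "omega2": 1.5},
        ]
    elif m == "M7":
        starts = [
            {"p": 0.5, "q": 1.0},
            {"p": float(rng.uniform(0.1, 3.0)), "q": float(rng.uniform(0.1, 3.0))},
            {"p": 2.0, "q": 2.0},
        ]
    elif m == "M8":
        starts = [
            {"p0": 0.85, "p": 0.5, "q": 1.0, "omega_s": 3.0},
            {
                "p0": float(rng.uniform(0.5, 0.95)),
                "p": float(rng.uniform(0.1, 3.0)),
                "q": float(rng.uniform(0.1, 3.0)),
                "omega_s": float(rng.uniform(1.2, 8.0)),
            },
            {"p0": 0.98, "p": 2.0, "q": 2.0, "omega_s": 1.05},
        ]
    elif m == "M8a":
        starts = [
            {"p0": 0.85, "p": 0.5, "q": 1.0},
            {
                "p0": float(rng.uniform(0.5, 0.95)),
                "p": float(rng.uniform(0.1, 3.0)),
                "q": float(rng.uniform(0.1, 3.0)),
            },
            {"p0": 0.98, "p": 2.0, "q": 2.0},
        ]
    return starts


def site_model_fit(
    caln: CodonAlignment,
    tree: Phylogeny,
    model: str,
    *,
    m0: CodonModelFit | None = None,
    frequencies: str = "F3x4",
    n_beta_categories: int = 10,
    extra_starts: list[dict] | None = None,
    seed: int = 0,
    maxiter: int = 300,
) -> CodonModelFit:
    """Fit one site-class mixture model (M1a, M2a, M7, M8 or M8a).

    Branch lengths are the M0 estimates times one free scale factor; the
    mixture parameters, kappa and the scale are optimised from several
    starting points and the best likelihood is kept. ``extra_starts`` lets a
    caller seed the optimiser with a nested null solution so the nested
    log-likelihood ordering holds exactly.
    """
    if model not in SITE_MODELS:
        raise ModelMismatchError(f"unknown site model {model!r}")
    if m0 is None:
        m0 = m0_fit(caln, tree, frequencies=frequencies)
    pi = FREQUENCY_MODELS[frequencies](caln)
    engine = CodonLikelihood(caln, tree, pi)
    base_bl = np.array([m0.branch_lengths[e] for e in engine.edges])
    spec = _MixtureSpec(model, n_beta_categories)
    rng = np.random.default_rng(seed)

    all_names = spec.names + ["kappa", "scale"]
    lo = np.array([spec.bounds[n][0] for n in all_names])
    hi = np.array([spec.bounds[n][1] for n in all_names])

    def negloglik(x):
        params = dict(zip(all_names, x))
        classes = spec.classes(params)
        bl = base_bl * params["scale"]
        ll = engine.loglik_mixture(params["kappa"], classes, bl)
        return -ll if np.isfinite(ll) else 1e12

    starts = _default_starts(spec, m0, rng)
    for st in extra_starts or []:
        starts.append(dict(st))
    best = None
    for st in starts:
        st = dict(st)
        st.setdefault("kappa", m0.kappa)
        st.setdefault("scale", 1.0)
        x0 = np.clip(np.array([st[n] for n in all_names]), lo, hi)
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"{model} optimisation diverged")
    params = dict(zip(all_names, best.x))
    classes = spec.classes(params)
    bl = base_bl * params["scale"]
    boundary = [
        n
        for n, v in params.items()
        if abs(v - spec.bounds[n][0]) < 1e-8 or abs(v - spec.bounds[n][1]) < 1e-8
    ]
    notes = f"boundary estimates: {boundary}" if boundary else ""
    kappa = params.pop("kappa")
    return _finish_fit(
        engine, model, -float(best.fun), kappa, params, classes, bl,
        bool(best.success), notes,
    )


def nested_start(null_fit: CodonModelFit, alt_model: str) -> dict:
    """Alternative-model start reproducing a nested null fit exactly."""
    p = null_fit.params
    if null_fit.model == "M1a" and alt_model == "M2a":
        return {
            "p0": p["p0"],
            "p1_rel": 1 - 1e-6,
            "omega0": p["omega0"],
            "omega2": 1.0,
            "kappa": null_fit.kappa,
            "scale": p.get("scale", 1.0),
        }
    if null_fit.model == "M7" and alt_model == "M8":
        return {
            "p0": 1 - 1e-6,
            "p": p["p"],
            "q": p["q"],
            "omega_s": 1.0,
            "kappa": null_fit.kappa,
            "scale": p.get("scale", 1.0),
        }
    if null_fit.model == "M8a" and alt_model == "M8":
        return {
            "p0": p["p0"],
            "p": p["p"],
            "q": p["q"],
            "omega_s": 1.0,
            "kappa": null_fit.kappa,
            "scale": p.get("scale", 1.0),
        }
    raise ModelMismatchError(
        f"{null_fit.model} is not a supported null for {alt_model}"
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(null: CodonModelFit, alt: CodonModelFit, df: int) -> LRTResult:
    """Likelihood-ratio test of nested codon models.

    The statistic 2(lnL_alt - lnL_null) is clipped at zero; a violation of
    the nesting order beyond 1e-6 raises :class:`OptimizationOrderError`.
    """
    stat = 2.0 * (alt.lnL - null.lnL)
    if stat < -1e-6:
        raise OptimizationOrderError(
            f"null {null.model} (lnL={null.lnL:.6f}) beats alternative "
            f"{alt.model} (lnL={alt.lnL:.6f})"
        )
    stat = max(stat, 0.0)
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


LRT_DF = {("M1a", "M2a"): 2, ("M7", "M8"): 2, ("M8a", "M8"): 1}


# ---------------------------------------------------------------------------
# Empirical-Bayes site identification
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionResult:
    """Per-site posterior membership in the positive-selection class."""

    model: str
    posteriors: np.ndarray  # (n_sites,)
    threshold: float
    site_columns: list[int]
    reference_protein: str

    @property
    def flagged(self) -> list[int]:
        """0-based codon-site indices with posterior >= threshold."""
        return [int(i) for i in np.where(self.posteriors >= self.threshold)[0]]

    def labels(self) -> list[str]:
        """Flagged sites as '<position><residue>' in reference coordinates."""
        return [
            f"{i + 1}{self.reference_protein[i]}" for i in self.flagged
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon_site": np.arange(1, len(self.posteriors) + 1),
                "alignment_column": self.site_columns,
                "reference_residue": list(self.reference_protein),
                "posterior": self.posteriors,
                "flagged": self.posteriors >= self.threshold,
            }
        )


def eb_sites(fit: CodonModelFit, threshold: float = 0.95) -> SiteSelectionResult:
    """Naive empirical-Bayes posteriors for the omega>1 class.

    Plugs the maximum-likelihood estimates into Bayes' rule per site (no
    averaging over parameter uncertainty). Requires a fit with a
    positive-selection class (M2a or M8 with omega_s > 1).
    """
    k = fit.positive_class_index
    if k is None:
        raise ModelMismatchError(
            f"model {fit.model} has no class with omega > 1"
        )
    post = fit.site_class_posteriors[:, k]
    return SiteSelectionResult(
        model=fit.model,
        posteriors=post,
        threshold=threshold,
        site_columns=fit.site_columns,
        reference_protein=fit.reference_protein,
    )


# ---------------------------------------------------------------------------
# Counting-based branch rates
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori potential sites for one sense codon, normalised so each
    nucleotide position contributes exactly one site (N + S = 3)."""
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if AMINO_ACID[mutant] == AMINO_ACID[codon]:
                syn += 1
        if valid == 0:
            n_sites += 1.0
            continue
        s_sites += syn / valid
        n_sites += 1.0 - syn / valid
    return n_sites, s_sites


_SITE_COUNTS = {c: _codon_site_counts(c) for c in SENSE_CODONS}


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average nonsynonymous/synonymous steps over shortest mutational
    pathways between two codons, skipping pathways through stop codons."""
    diff = [k for k in range(3) if a[k] != b[k]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        nd = sd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                nd += 1  # treat steps at stop codons as nonsynonymous
            elif AMINO_ACID[cur] == AMINO_ACID[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((nd, sd))
    pool = valid if valid else fallback
    nd = sum(x for x, _ in pool) / len(pool)
    sd = sum(y for _, y in pool) / len(pool)
    return nd, sd


def _ancestral_nucleotides(caln: CodonAlignment, tree: Phylogeny) -> dict[str, str]:
    """Per-nucleotide Fitch reconstruction; top-down ambiguities resolve
    toward the parent state (root ties toward the alphabetically first)."""
    tip_seq = {
        t: "".join(SENSE_CODONS[c] for c in caln.codes[caln.taxa.index(t)])
        for t in tree.tip_labels()
    }
    n_nt = 3 * caln.n_codons
    seqs = {t: list(s) for t, s in tip_seq.items()}
    anc: dict[str, list[str]] = {
        n.name: [""] * n_nt for n in tree.preorder() if not n.is_tip
    }
    post = [n for n in tree.postorder()]
    pre = [n for n in tree.preorder()]
    for site in range(n_nt):
        sets: dict[str, frozenset] = {}
        for node in post:
            if node.is_tip:
                sets[node.name] = frozenset(seqs[node.name][site])
            else:
                inter = None
                union = frozenset()
                for c in node.children:
                    s = sets[c.name]
                    inter = s if inter is None else (inter & s)
                    union |= s
                sets[node.name] = inter if inter else union
        for node in pre:
            if node.is_tip:
                continue
            options = sets[node.name]
            if node.parent is not None:
                parent_state = anc[node.parent.name][site]
                if parent_state in options:
                    anc[node.name][site] = parent_state
                    continue
            anc[node.name][site] = min(options)
    out = {name: "".join(chars) for name, chars in anc.items()}
    out.update(tip_seq)
    return out


@dataclass
class BranchRates:
    """Per-branch counting estimates of dN and dS (Nei–Gojobori with
    Jukes–Cantor correction)."""

    data: pd.DataFrame  # index: branch (child label)
    method: str = "ancestral parsimony + Nei-Gojobori counting"

    def dn(self, branch: str) -> float:
        return float(self.data.loc[branch, "dN"])

    def ds(self, branch: str) -> float:
        return float(self.data.loc[branch, "dS"])


def _jc_correct(p: float) -> tuple[float, bool]:
    if p <= 0:
        return 0.0, False
    if p >= 0.75:
        return p, True  # saturated: report the raw proportion, flagged
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def branch_rates_counting(caln: CodonAlignment, tree: Phylogeny) -> BranchRates:
    """Counting branch rates: reconstruct ancestral sequences by parsimony,
    then count synonymous/nonsynonymous changes per branch."""
    seqs = _ancestral_nucleotides(caln, tree)
    rows = []
    for child in tree.edges():
        parent = child.parent
        sp, sc = seqs[parent.name], seqs[child.name]
        nd = sd = 0.0
        n_sites = s_sites = 0.0
        for i in range(0, len(sc), 3):
            ccod = sc[i : i + 3]
            if ccod in _SITE_COUNTS:
                n_c, s_c = _SITE_COUNTS[ccod]
            else:  # reconstructed stop codon: every position a nonsyn site
                n_c, s_c = 3.0, 0.0
            n_sites += n_c
            s_sites += s_c
            d_nd, d_sd = _pathway_counts(sp[i : i + 3], ccod)
            nd += d_nd
            sd += d_sd
        pn = nd / n_sites if n_sites else 0.0
        ps = sd / s_sites if s_sites else 0.0
        dn, sat_n = _jc_correct(pn)
        ds, sat_s = _jc_correct(ps)
        rows.append(
            {
                "branch": child.name,
                "Nd": nd,
                "Sd": sd,
                "N": n_sites,
                "S": s_sites,
                "dN": dn,
                "dS": ds,
                "saturated": sat_n or sat_s,
            }
        )
    df = pd.DataFrame(rows).set_index("branch")
    return BranchRates(df)


@dataclass
class LineageOmega:
    """Root-to-tip accumulated dN/dS for one terminal species."""

    tip: str
    sum_dn: float
    sum_ds: float

    @property
    def omega(self) -> float | None:
        if self.sum_ds == 0:
            return None
        return self.sum_dn / self.sum_ds

    @property
    def defined(self) -> bool:
        return self.sum_ds > 0


def lineage_omega(rates: BranchRates, tree: Phylogeny, tip: str) -> LineageOmega:
    """Sum dN and dS along the root-to-tip path and take the ratio.

    Summing from the common ancestor gives every lineage the same time
    depth, so the ratio is not confounded by branch-duration effects.
    """
    path = tree.path_to_root(tip)
    sum_dn = sum(rates.dn(n.name) for n in path)
    sum_ds = sum(rates.ds(n.name) for n in path)
    out = LineageOmega(tip, sum_dn, sum_ds)
    if not out.defined:
        logger.warning("lineage omega undefined for %s (sum dS = 0)", tip)
    return out


def lineage_omegas(
    rates: BranchRates, tree: Phylogeny, *, include_outgroup: bool = False
) -> pd.DataFrame:
    tips = tree.tip_labels() if include_outgroup else tree.ingroup_tip_labels()
    rows = []
    for t in tips:
        lo = lineage_omega(rates, tree, t)
        rows.append(
            {
                "species": t,
                "sum_dN": lo.sum_dn,
                "sum_dS": lo.sum_ds,
                "omega_root_to_tip": lo.omega if lo.defined else np.nan,
                "defined": lo.defined,
            }
        )
    return pd.DataFrame(rows)


def fits_to_table(fits: list[CodonModelFit]) -> pd.DataFrame:
    """Model-comparison table (one row per fitted model)."""
    rows = []
    for f in fits:
        desc = ", ".join(
            f"{k}={v:.4g}" for k, v in sorted(f.params.items())
        )
        rows.append(
            {
                "model": f.model,
                "lnL": f.lnL,
                "kappa": f.kappa,
                "parameters": desc,
                "classes": "; ".join(
                    f"p={p:.3f},w={w:.3f}" for p, w in f.classes
                ),
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
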