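"""Synthetic study generator with complete ground-truth bookkeeping.

Emulates the structure of the real study: a rooted 16-species ingroup plus
outgroup, per-species codon sequences (~320 codons) evolved under a codon
substitution model with superimposed in-frame (3n nt) insertion/deletion
events biased toward deletions, at least three sequenced individuals per
species carrying substitution-only polymorphism, and phenotypes in which
log testes mass scales allometrically with log body mass plus a
phylogenetically structured sperm-competition deviation that is negatively
coupled to sequence length, while sperm velocity descriptors decrease with
sequence length on top of factor-structured noise (so their first principal
component carries the programmed signal).

The simulator emits the true alignment directly from its own coordinate
bookkeeping — alignment construction is out of scope, so no realignment
step can corrupt the ground truth. Substitutions are drawn from the exact
transition probabilities ``P(t) = expm(Qt)`` per branch, which is
distributionally identical to event-by-event simulation of the same chain.
Indel events that coalesce within a single branch (overlapping or adjacent
spans) are recorded as the single realized mutation they produce.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .codon_evolution import (
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    codon_rate_matrix,
    rate_matrix_mean_rate,
    _Eigen,
)
from .errors import SimulationDegenerateError
from .io_formats import (
    VELOCITY_DESCRIPTORS,
    GappedAlignment,
    Node,
    PhenotypeTable,
    Phylogeny,
    SequenceRecord,
    validate_phenotypes,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_species: int = 16
    outgroup_name: str = "Outgroup"
    n_codons: int = 320
    kappa: float = 2.0
    omega: float = 0.4
    # optional mixture: list of (proportion, omega); overrides `omega`
    site_classes: list[tuple[float, float]] | None = None
    tree_depth: float = 0.3  # ingroup root-to-tip, expected subs/codon
    outgroup_stem_fraction: float = 0.3
    indel_rate: float = 1.0  # expected indel events per branch
    deletion_bias: float = 0.6  # P(event is a deletion)
    indel_length_codons: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.1}
    )
    individuals_per_species: int = 3
    polymorphic_substitutions_max: int = 2
    # phenotypes
    rtm_a: float = 0.031  # rodent testes allometry coefficient (g)
    rtm_b: float = 0.77  # rodent testes allometry exponent
    log_body_mean: float = 3.4  # ln grams (~30 g)
    body_bm_sigma: float = 0.8
    sperm_competition_sigma: float = 0.5
    length_rtm_coupling: float = 0.8  # corr(u, -length); 0 disables
    lambda_true: float = 0.5
    beta_length_velocity: float = -1.5  # um/s per amino acid, VCL scale
    velocity_factor_sigma: float = 1.0
    males_per_species: int = 5

    def validate(self) -> None:
        if self.n_species < 3:
            raise SimulationDegenerateError("need at least 3 ingroup species")
        if self.indel_rate < 0 or self.deletion_bias < 0 or self.deletion_bias > 1:
            raise SimulationDegenerateError("invalid indel parameters")
        if any(k <= 0 for k in self.indel_length_codons):
            raise SimulationDegenerateError("indel lengths must be positive codons")


@dataclass
class GroundTruth:
    """Everything the simulator knows about what it generated."""

    config: dict
    seed: int
    tree_newick: str
    events: pd.DataFrame  # branch, kind, length_nt, columns
    true_lengths: pd.DataFrame  # species, nt_length, aa_length
    selected_sites: list[int]  # 0-based codon sites with omega > 1
    # identity of each final alignment codon column: original root codon ids
    # are < n_codons, inserted material gets fresh ids
    alignment_columns: list[int] = field(default_factory=list)
    phenotype_params: dict = field(default_factory=dict)
    phenotype_values: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "tree_newick": self.tree_newick,
            "events": self.events.to_dict(orient="records"),
            "true_lengths": self.true_lengths.to_dict(orient="records"),
            "selected_sites": self.selected_sites,
            "phenotype_params": self.phenotype_params,
        }
        return json.dumps(payload, indent=1, default=str)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig, seed: int) -> Phylogeny:
    """Pure-birth ingroup topology rescaled to the configured depth, with
    the outgroup attached below the ingroup root."""
    config.validate()
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:02d}" for i in range(config.n_species)]
    )
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    dtree.seed_node.edge.length = 0.0
    depth = max(
        leaf.distance_from_root() for leaf in dtree.leaf_node_iter()
    )
    # the birth-death process stops at the n-th speciation, so the two
    # newest tips have zero-length branches; extend every terminal branch
    # by a fixed fraction of the depth to keep all sister pairs divergent
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.1 * depth
    depth *= 1.1
    scale = config.tree_depth / depth if depth > 0 else 1.0
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    ingroup = Phylogeny.from_dendropy(dtree)
    stem = config.outgroup_stem_fraction * config.tree_depth
    root = Node("", 0.0)
    og = Node(config.outgroup_name, config.tree_depth + stem)
    ingroup_root = ingroup.root
    ingroup_root.length = stem
    root.add_child(og)
    root.add_child(ingroup_root)
    return Phylogeny(root, outgroup=config.outgroup_name)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _sample_categories(probs: np.ndarray, n: int, rng) -> np.ndarray:
    return rng.choice(len(probs), size=n, p=probs / probs.sum())


def _evolve_codons(
    parent_codes: np.ndarray,
    t: float,
    eigens: dict[float, _Eigen],
    rates: dict[float, float],
    site_omega: np.ndarray,
    rng,
) -> np.ndarray:
    """Draw child codons from the exact transition kernel per site class."""
    child = parent_codes.copy()
    for w, eig in eigens.items():
        mask = site_omega == w
        if not mask.any():
            continue
        P = eig.transition(t / rates["__mean__"])
        cum = np.cumsum(P, axis=1)
        idx = np.where(mask)[0]
        u = rng.random(len(idx))
        for pos, uu in zip(idx, u):
            child[pos] = np.searchsorted(cum[parent_codes[pos]], uu)
    return np.clip(child, 0, N_SENSE - 1)


def simulate_sequences(
    tree: Phylogeny, config: SimulationConfig, seed: int
) -> tuple[GappedAlignment, GroundTruth]:
    """Evolve codon sequences with indels along the tree.

    Returns the individual-level gapped alignment (``species|indN`` record
    ids, one record for the outgroup) and the ground truth: realized indel
    events per branch, true ungapped lengths, and the true positively
    selected site set (empty under the one-ratio default).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    pi = np.full(N_SENSE, 1.0 / N_SENSE)

    if config.site_classes:
        props = np.array([p for p, _ in config.site_classes])
        omegas = [w for _, w in config.site_classes]
    else:
        props = np.array([1.0])
        omegas = [config.omega]
    class_of_site = _sample_categories(props, config.n_codons, rng)
    site_omega = np.array([omegas[k] for k in class_of_site])
    selected_sites = [int(s) for s in np.where(site_omega > 1.0)[0]]

    eigens: dict[float, _Eigen] = {}
    class_rates: dict[float, float] = {}
    for w in set(omegas):
        Q = codon_rate_matrix(config.kappa, w, pi, scale=False)
        eigens[w] = _Eigen(Q, pi)
        class_rates[w] = rate_matrix_mean_rate(config.kappa, w, pi)
    mean_rate = float(
        sum(p * class_rates[w] for p, w in zip(props, omegas))
    )
    class_rates["__mean__"] = mean_rate

    # global alignment column bookkeeping (codon-level columns)
    next_col = config.n_codons
    global_order: list[int] = list(range(config.n_codons))
    root_codes = rng.integers(0, N_SENSE, size=config.n_codons)
    root_seq = list(zip(range(config.n_codons), root_codes.tolist()))

    length_probs = np.array(list(config.indel_length_codons.values()), dtype=float)
    length_vals = list(config.indel_length_codons.keys())

    seqs: dict[str, list[tuple[int, int]]] = {tree.root.name: root_seq}
    raw_events: list[dict] = []

    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[node.parent.name]
        cols = [c for c, _ in parent_seq]
        codes = np.array([x for _, x in parent_seq])
        # per-site omegas follow the original column identity when possible;
        # inserted material evolves at the mixture-average (class 0) rate
        omega_per_site = np.array(
            [
                site_omega[c] if c < config.n_codons else omegas[0]
                for c in cols
            ]
        )
        codes = _evolve_codons(
            codes, node.length, eigens, class_rates, omega_per_site, rng
        )
        seq = list(zip(cols, codes.tolist()))

        n_events = rng.poisson(config.indel_rate)
        for _ in range(n_events):
            k = length_vals[_sample_categories(length_probs, 1, rng)[0]]
            if rng.random() < config.deletion_bias and len(seq) > k + 2:
                # deletion avoiding the first and last codon
                start = int(rng.integers(1, len(seq) - k))
                del seq[start : start + k]
            else:
                ins_cols = list(range(next_col, next_col + k))
                next_col += k
                pos = int(rng.integers(1, len(seq)))
                anchor = seq[pos - 1][0]
                gpos = global_order.index(anchor) + 1
                global_order[gpos:gpos] = ins_cols
                new_codons = rng.integers(0, N_SENSE, size=k)
                seq[pos:pos] = list(zip(ins_cols, new_codons.tolist()))
        if len(seq) < 3:
            raise SimulationDegenerateError(
                f"sequence on branch {node.name} nearly fully deleted"
            )
        seqs[node.name] = seq

        # realized events: contiguous runs of removed / added columns
        parent_cols = [c for c, _ in parent_seq]
        child_cols = [c for c, _ in seq]
        child_set = set(child_cols)
        parent_set = set(parent_cols)
        removed = [c for c in parent_cols if c not in child_set]
        added = [c for c in child_cols if c not in parent_set]
        for run_cols, kind, ref in (
            (removed, "deletion", parent_cols),
            (added, "insertion", child_cols),
        ):
            if not run_cols:
                continue
            pos_of = {c: i for i, c in enumerate(ref)}
            run: list[int] = []
            prev = None
            for c in run_cols:
                if prev is not None and pos_of[c] != prev + 1:
                    raw_events.append(
                        {"branch": node.name, "kind": kind,
                         "length_nt": 3 * len(run), "columns": list(run)}
                    )
                    run = []
                run.append(c)
                prev = pos_of[c]
            raw_events.append(
                {"branch": node.name, "kind": kind,
                 "length_nt": 3 * len(run), "columns": list(run)}
            )

    # assemble final alignment over columns observed in at least one tip
    tip_names = tree.tip_labels()
    observed: set[int] = set()
    for t in tip_names:
        observed.update(c for c, _ in seqs[t])
    kept = [c for c in global_order if c in observed]
    col_pos = {c: i for i, c in enumerate(kept)}

    def to_string(seq: list[tuple[int, int]]) -> str:
        chars = ["---"] * len(kept)
        for c, code in seq:
            chars[col_pos[c]] = SENSE_CODONS[code]
        return "".join(chars)

    records: list[SequenceRecord] = []
    species_map: dict[str, str] = {}
    for t in tip_names:
        base = seqs[t]
        if t == tree.outgroup:
            rid = t
            records.append(SequenceRecord(rid, to_string(base), is_outgroup=True))
            species_map[rid] = t
            continue
        for i in range(config.individuals_per_species):
            indiv = [list(x) for x in base]
            n_poly = int(rng.integers(0, config.polymorphic_substitutions_max + 1))
            for _ in range(n_poly):
                pos = int(rng.integers(0, len(indiv)))
                cur = SENSE_CODONS[indiv[pos][1]]
                neighbours = [
                    CODON_INDEX[c]
                    for c in SENSE_CODONS
                    if sum(a != b for a, b in zip(c, cur)) == 1
                ]
                indiv[pos][1] = int(rng.choice(neighbours))
            rid = f"{t}|ind{i + 1}"
            records.append(
                SequenceRecord(rid, to_string([tuple(x) for x in indiv]))
            )
            species_map[rid] = t
    aln = GappedAlignment(records, species_map)

    events = pd.DataFrame(
        raw_events, columns=["branch", "kind", "length_nt", "columns"]
    )
    lengths = pd.DataFrame(
        [
            {
                "species": t,
                "nt_length": 3 * len(seqs[t]),
                "aa_length": len(seqs[t]),
            }
            for t in tip_names
        ]
    )
    truth = GroundTruth(
        config=asdict(config),
        seed=seed,
        tree_newick=tree.to_newick(),
        events=events,
        true_lengths=lengths,
        selected_sites=selected_sites,
        alignment_columns=list(kept),
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

_VEL_BASELINE = {
    "VCL": 130.0, "VSL": 60.0, "VAP": 85.0, "LIN": 50.0,
    "STR": 70.0, "ALH": 3.0, "BCF": 10.0,
}
# common-factor loadings: the three principal velocities load strongly so
# PC1 is an overall-velocity axis
_VEL_LOADING = {
    "VCL": 20.0, "VSL": 15.0, "VAP": 17.0, "LIN": 4.0,
    "STR": 3.0, "ALH": 0.4, "BCF": 0.8,
}
# relative sensitivity of each descriptor to sequence length
_VEL_LENGTH_SCALE = {
    "VCL": 1.0, "VSL": 0.8, "VAP": 0.9, "LIN": 0.25,
    "STR": 0.2, "ALH": 0.02, "BCF": 0.04,
}
_VEL_NOISE = {
    "VCL": 8.0, "VSL": 6.0, "VAP": 7.0, "LIN": 3.0,
    "STR": 2.5, "ALH": 0.3, "BCF": 0.6,
}


def _phylo_deviate(tree: Phylogeny, species: list[str], lam: float, rng) -> np.ndarray:
    """Unit-variance deviate with Pagel-lambda phylogenetic structure."""
    V = tree.prune_to(species).brownian_covariance(species).values
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)  # correlation-scaled Brownian structure
    Cl = lam * C
    np.fill_diagonal(Cl, 1.0)
    L = np.linalg.cholesky(Cl + 1e-10 * np.eye(len(species)))
    return L @ rng.standard_normal(len(species))


def simulate_phenotypes(
    tree: Phylogeny,
    lengths: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Phenotypes with programmed effect structure.

    Log body mass is Brownian on the tree; testes mass follows the
    allometry ``a * body**b`` times ``exp(s * u)`` where ``u`` is a
    lambda-structured sperm-competition deviate correlated with shorter
    sequences; each velocity descriptor declines with sequence length and
    shares a common factor so PC1 carries the signal.
    """
    rng = np.random.default_rng(seed)
    species = [s for s in tree.ingroup_tip_labels()]
    len_s = lengths.set_index("species").loc[species, "aa_length"].astype(float)
    z_len = (len_s - len_s.mean()) / (len_s.std(ddof=1) or 1.0)

    V = tree.prune_to(species).brownian_covariance(species).values
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(species)))
    log_body = config.log_body_mean + config.body_bm_sigma * (
        Lc @ rng.standard_normal(len(species))
    )
    body = np.exp(log_body)

    rho = config.length_rtm_coupling
    u_indep = _phylo_deviate(tree, species, config.lambda_true, rng)
    u = rho * (-z_len.values) + np.sqrt(max(0.0, 1 - rho**2)) * u_indep
    testes = config.rtm_a * body**config.rtm_b * np.exp(
        config.sperm_competition_sigma * u
    )

    f = config.velocity_factor_sigma * rng.standard_normal(len(species))
    dlen = (len_s - len_s.mean()).values
    vel = {}
    for dsc in VELOCITY_DESCRIPTORS:
        mu = (
            _VEL_BASELINE[dsc]
            + config.beta_length_velocity * _VEL_LENGTH_SCALE[dsc] * dlen
            + _VEL_LOADING[dsc] * f
            + _VEL_NOISE[dsc] * rng.standard_normal(len(species))
        )
        if dsc in ("LIN", "STR"):
            mu = np.clip(mu, 1.0, 99.0)
        else:
            mu = np.clip(mu, 0.1, None)
        vel[dsc] = mu

    df = pd.DataFrame({"species": species, "body_mass": body, "testes_mass": testes})
    for dsc in VELOCITY_DESCRIPTORS:
        df[dsc] = vel[dsc]
    table = validate_phenotypes(df, tree=tree, source="<simulated>")

    males = []
    for i, sp in enumerate(species):
        for m in range(config.males_per_species):
            row = {"species": sp, "male": m + 1}
            for dsc in VELOCITY_DESCRIPTORS:
                row[dsc] = float(
                    vel[dsc][i] + 0.25 * _VEL_NOISE[dsc] * rng.standard_normal()
                )
            males.append(row)

    truth = GroundTruth(
        config=asdict(config),
        seed=seed,
        tree_newick=tree.to_newick(),
        events=pd.DataFrame(columns=["branch", "kind", "length_nt", "columns"]),
        true_lengths=lengths,
        selected_sites=[],
        phenotype_params={
            "rtm_a": config.rtm_a,
            "rtm_b": config.rtm_b,
            "length_rtm_coupling": rho,
            "lambda_true": config.lambda_true,
            "beta_length_velocity": config.beta_length_velocity,
            "u": dict(zip(species, u.tolist())),
        },
        phenotype_values=pd.DataFrame(males),
    )
    return table, truth


def simulate_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> dict[str, object]:
    """Full synthetic study: tree, alignment with indels, phenotypes."""
    config = config or SimulationConfig()
    tree = simulate_tree(config, seed)
    aln, seq_truth = simulate_sequences(tree, config, seed + 1)
    phenotypes, phen_truth = simulate_phenotypes(
        tree, seq_truth.true_lengths, config, seed + 2
    )
    seq_truth.phenotype_params = phen_truth.phenotype_params
    seq_truth.phenotype_values = phen_truth.phenotype_values
    return {
        "config": config,
        "tree": tree,
        "alignment": aln,
        "phenotypes": phenotypes,
        "truth": seq_truth,
    }
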