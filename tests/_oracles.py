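"""Independent oracles used by the tests.

Everything here is deliberately brute force and shares no code with the
package's own algorithms: parsimony scores by exhaustive enumeration of
ancestral assignments, codon likelihoods by summing over all interior-node
codon states with scipy's generic matrix exponential, and pathway counting
by explicit recursion.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.linalg import expm

SENSE = sorted(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
AA = dict(standard_dna_table.forward_table)
IDX = {c: i for i, c in enumerate(SENSE)}


# ---------------------------------------------------------------------------
# Exhaustive small parsimony
# ---------------------------------------------------------------------------

def exhaustive_parsimony_score(tree, states: dict[str, str]) -> int:
    """Minimum change count over all ancestral 0/1 assignments.

    '?' tips may take either state (they are assigned too, like PAUP's
    treatment of missing data).
    """
    internals = [n for n in tree.preorder() if not n.is_tip]
    tips = tree.tips()
    free_tips = [t for t in tips if states[t.name] == "?"]
    best = None
    for internal_assign in itertools.product("01", repeat=len(internals)):
        lookup = {n.name: s for n, s in zip(internals, internal_assign)}
        for tip_assign in itertools.product("01", repeat=len(free_tips)):
            assign = dict(lookup)
            for t in tips:
                assign[t.name] = states[t.name]
            for t, s in zip(free_tips, tip_assign):
                assign[t.name] = s
            changes = sum(
                assign[n.name] != assign[n.parent.name]
                for n in tree.preorder()
                if n.parent is not None
            )
            if best is None or changes < best:
                best = changes
    return best


# ---------------------------------------------------------------------------
# Brute-force codon likelihood
# ---------------------------------------------------------------------------

def _is_ts(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def brute_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled GY rate matrix built with plain loops."""
    n = len(SENSE)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE):
        for j, cj in enumerate(SENSE):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            r = pi[j]
            if _is_ts(ci[k], cj[k]):
                r *= kappa
            if AA[ci] != AA[cj]:
                r *= omega
            Q[i, j] = r
        Q[i, i] = -Q[i].sum()
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def brute_force_loglik(
    tree,
    codon_rows: dict[str, list[str]],
    kappa: float,
    omega: float,
    branch_lengths: dict[str, float],
    pi: np.ndarray,
) -> float:
    """Log-likelihood by summation over every interior-node codon state."""
    Q = brute_rate_matrix(kappa, omega, pi)
    P = {
        name: expm(Q * t) for name, t in branch_lengths.items()
    }
    internals = [n for n in tree.preorder() if not n.is_tip]
    tips = tree.tips()
    n_sites = len(next(iter(codon_rows.values())))
    total = 0.0
    n = len(SENSE)
    for site in range(n_sites):
        site_like = 0.0
        for assign in itertools.product(range(n), repeat=len(internals)):
            state = {nd.name: s for nd, s in zip(internals, assign)}
            for t in tips:
                state[t.name] = IDX[codon_rows[t.name][site]]
            prob = pi[state[tree.root.name]]
            for nd in tree.preorder():
                if nd.parent is None:
                    continue
                prob *= P[nd.name][state[nd.parent.name], state[nd.name]]
            site_like += prob
        total += np.log(site_like)
    return float(total)


# ---------------------------------------------------------------------------
# Pathway counting
# ---------------------------------------------------------------------------

def pathway_counts_oracle(a: str, b: str) -> tuple[float, float]:
    """Nei–Gojobori pathway averaging by explicit permutation walk."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    clean, dirty = [], []
    for order in itertools.permutations(diffs):
        cur, nd, sd, via_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                via_stop = True
            if nxt in STOPS or cur in STOPS:
                nd += 1
            elif AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if via_stop else clean).append((nd, sd))
    pool = clean or dirty
    return (
        sum(x for x, _ in pool) / len(pool),
        sum(y for _, y in pool) / len(pool),
    )
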