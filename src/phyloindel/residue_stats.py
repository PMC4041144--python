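"""Histidine-content analysis of the translated N-terminal sequences.

The N-terminal intracellular domain studied here is unusually histidine
rich, which is thought to underlie pH sensing by the channel. This module
counts histidines per species, reconstructs ancestral histidine proportions
on the tree (squared-change parsimony weighted by branch lengths), reports
branches with large parent-to-child shifts, and measures the overlap
between positively selected sites and histidine-bearing positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_evolution import CodonAlignment, SiteSelectionResult
from .errors import AlphabetError, CoordinateError
from .io_formats import Phylogeny

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ResidueContent:
    species: str
    histidine_count: int
    aa_length: int

    @property
    def histidine_proportion(self) -> float:
        return self.histidine_count / self.aa_length


def histidine_content(protein: str, species: str = "") -> ResidueContent:
    """Count histidines in an ungapped amino-acid sequence."""
    if not protein:
        raise AlphabetError("empty protein sequence")
    bad = set(protein.upper()) - AMINO_ACIDS
    if bad:
        raise AlphabetError(f"illegal residues {sorted(bad)} (gaps not allowed)")
    seq = protein.upper()
    return ResidueContent(species, seq.count("H"), len(seq))


def histidine_table(proteins: dict[str, str]) -> pd.DataFrame:
    rows = []
    for sp, seq in proteins.items():
        rc = histidine_content(seq, sp)
        rows.append(
            {
                "species": sp,
                "histidine_count": rc.histidine_count,
                "aa_length": rc.aa_length,
                "histidine_proportion": rc.histidine_proportion,
            }
        )
    return pd.DataFrame(rows)


def _squared_change_ancestors(
    tip_values: dict[str, float], tree: Phylogeny
) -> dict[str, float]:
    """Ancestral values minimising sum of (child - parent)^2 / branch length.

    Solved exactly as a weighted-Laplacian linear system; zero-length
    branches get a small floor so the system stays well posed.
    """
    internals = [n for n in tree.preorder() if not n.is_tip]
    idx = {n.name: i for i, n in enumerate(internals)}
    m = len(internals)
    A = np.zeros((m, m))
    rhs = np.zeros(m)
    floor = max(
        1e-8, 1e-6 * np.mean([e.length for e in tree.edges()] or [1.0])
    )
    for node in internals:
        i = idx[node.name]
        for child in node.children:
            w = 1.0 / max(child.length, floor)
            A[i, i] += w
            if child.is_tip:
                rhs[i] += w * tip_values[child.name]
            else:
                A[i, idx[child.name]] -= w
        if node.parent is not None:
            w = 1.0 / max(node.length, floor)
            A[i, i] += w
            A[i, idx[node.parent.name]] -= w
    vals = np.linalg.solve(A, rhs)
    out = {n.name: float(vals[idx[n.name]]) for n in internals}
    out.update(tip_values)
    return out


@dataclass
class ShiftReport:
    """Branches whose parent-to-child change in reconstructed histidine
    proportion exceeds the threshold, largest first."""

    data: pd.DataFrame  # branch, parent, change, direction
    threshold: float
    ancestral: dict[str, float]

    @property
    def gains(self) -> pd.DataFrame:
        return self.data[self.data["direction"] == "gain"]

    @property
    def losses(self) -> pd.DataFrame:
        return self.data[self.data["direction"] == "loss"]


def content_shifts_on_tree(
    contents: pd.DataFrame, tree: Phylogeny, threshold: float = 0.02
) -> ShiftReport:
    """Rank branches by reconstructed change in histidine proportion.

    ``contents`` needs columns ``species`` and ``histidine_proportion`` for
    every tip. The default threshold (2 percentage points) separates clade
    level gains/losses from drift-scale noise.
    """
    tip_values = dict(
        zip(contents["species"], contents["histidine_proportion"].astype(float))
    )
    missing = set(tree.tip_labels()) - set(tip_values)
    if missing:
        raise CoordinateError(f"no histidine proportion for tips {sorted(missing)}")
    anc = _squared_change_ancestors(tip_values, tree)
    rows = []
    for child in tree.edges():
        change = anc[child.name] - anc[child.parent.name]
        if abs(change) > threshold:
            rows.append(
                {
                    "branch": child.name,
                    "parent": child.parent.name,
                    "change": change,
                    "direction": "gain" if change > 0 else "loss",
                }
            )
    rows.sort(key=lambda r: -abs(r["change"]))
    return ShiftReport(
        pd.DataFrame(rows, columns=["branch", "parent", "change", "direction"]),
        threshold,
        anc,
    )


def positive_site_histidine_overlap(
    sites: SiteSelectionResult,
    caln: CodonAlignment,
    *,
    mode: str = "any",
) -> tuple[float, int, int]:
    """Fraction of flagged positively selected sites at histidine positions.

    ``mode="any"`` counts a site when any taxon carries H there (the default
    reading of "positions containing histidines"); ``mode="reference"``
    restricts to the reference species' residue. Returns
    (fraction, histidine_hits, flagged_total); an empty flagged set yields
    fraction 0 with total 0.
    """
    flagged = sites.flagged
    if not flagged:
        return 0.0, 0, 0
    if len(sites.posteriors) != caln.n_codons:
        raise CoordinateError(
            "site posteriors and codon alignment differ in length"
        )
    hits = 0
    for s in flagged:
        if mode == "reference":
            has_h = sites.reference_protein[s] == "H"
        else:
            has_h = any(
                caln.residue(t, s) == "H" for t in caln.taxa
            )
        hits += has_h
    return hits / len(flagged), hits, len(flagged)
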