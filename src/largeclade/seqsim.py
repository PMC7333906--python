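"""Strict-clock sequence simulation along an ultrametric tree.

Substitutions occur as a homogeneous Poisson process at ``subst_rate`` per
site per Myr (the total rate away from the current base); each event replaces
the base with one of the other three uniformly, i.e. one third of the total
rate per alternative.  This is the Jukes–Cantor model simulated at the event
level: the number of events on a branch of duration ``t`` is
Poisson(``subst_rate * t``) per site, applied sequentially.  The matching
transition-probability closed form lives in :mod:`largeclade.clockinfer`,
which keeps simulation and likelihood as independent code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import UltrametricTree

__all__ = ["ClockModel", "Alignment", "simulate_alignment"]

BASES = np.array(list("ACGT"))
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock: substitutions per site per Myr on every branch."""

    subst_rate: float

    def __post_init__(self) -> None:
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be non-negative")


@dataclass
class Alignment:
    """Nucleotide matrix (taxa x sites) tied to tree tip labels.

    ``codes`` holds bases as integers 0..3 = A, C, G, T.
    """

    taxa: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 3):
            raise ValueError("codes must be in 0..3 (ACGT)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(BASES[self.codes[self.taxa.index(taxon)]])

    # -- I/O ---------------------------------------------------------------
    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq("".join(BASES[row])), id=name, description="")
            for name, row in zip(self.taxa, self.codes)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            taxa.append(rec.id)
            rows.append(cls._encode(str(rec.seq)))
        return cls(taxa, np.array(rows, dtype=np.int8))

    def to_nexus(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_sites};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            for name, row in zip(self.taxa, self.codes):
                fh.write(f"    {name}  {''.join(BASES[row])}\n")
            fh.write("  ;\nEND;\n")

    @classmethod
    def from_nexus(cls, path: str) -> "Alignment":
        import dendropy

        mat = dendropy.DnaCharacterMatrix.get(path=path, schema="nexus")
        taxa, rows = [], []
        for taxon in mat.taxon_namespace:
            taxa.append(taxon.label)
            rows.append(cls._encode(str(mat[taxon])))
        return cls(taxa, np.array(rows, dtype=np.int8))

    @staticmethod
    def _encode(seq: str) -> np.ndarray:
        try:
            return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"non-ACGT character in sequence: {exc}") from exc


def simulate_alignment(
    tree: UltrametricTree,
    n_sites: int,
    clock: ClockModel,
    seed: int | np.random.Generator | None = None,
) -> Alignment:
    """Evolve ``n_sites`` independent sites down ``tree`` under the clock.

    Root states are uniform on {A, C, G, T}.  On each branch the per-site
    event count is Poisson(rate x duration); events are applied one at a
    time, each replacing the base with one of the other three uniformly.
    """
    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    root = tree.root
    states[root] = rng.integers(0, 4, n_sites, dtype=np.int8)
    # preorder: parents before children
    for v in tree.postorder_internal()[::-1]:
        for c in tree.children[v]:
            c = int(c)
            t = tree.ages[v] - tree.ages[c]
            s = states[v].copy()
            n_events = rng.poisson(clock.subst_rate * t, n_sites)
            for k in range(1, int(n_events.max()) + 1 if n_events.size else 0):
                hit = n_events >= k
                jumps = rng.integers(1, 4, int(hit.sum()), dtype=np.int8)
                s[hit] = (s[hit] + jumps) % 4
            states[c] = s
    return Alignment(list(tree.tip_labels), states[: tree.n_tips])
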