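"""Sequence-level likelihood P(D | G, l) by the peeling algorithm.

Nucleotide data only; gaps, N and any ambiguity code are treated as
missing (all-ones conditionals).  JC69 is the default model; GTR is
supported through eigendecomposition of the reversible rate matrix.  Rate
matrices are normalised to one expected substitution per unit length, so
gene-tree edge lengths are expected substitutions per site.  There is no
among-site rate variation: the relaxed clock of the evolution model acts
on edges, not sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _kernels
from .trees import GeneTree

__all__ = ["MSA", "SubstitutionModel", "JC69", "peeling_likelihood"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
BASES = "ACGT"
MISSING = 4


@dataclass
class MSA:
    """Aligned nucleotide sequences, one per gene leaf.

    ``codes`` is (n_seq, n_col) with 0..3 = ACGT and 4 = missing.
    """

    labels: list
    codes: np.ndarray

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_strings(cls, seqs: dict) -> "MSA":
        labels = list(seqs)
        ncol = {len(s) for s in seqs.values()}
        if len(ncol) != 1:
            raise ValueError("sequences have unequal lengths")
        codes = np.full((len(labels), ncol.pop()), MISSING, dtype=np.int8)
        for i, lbl in enumerate(labels):
            for j, ch in enumerate(seqs[lbl].upper()):
                codes[i, j] = _CODE.get(ch, MISSING)
        return cls(labels, codes)

    @classmethod
    def read_fasta(cls, source) -> "MSA":
        handle = source if hasattr(source, "read") else open(source)
        try:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        finally:
            if handle is not source:
                handle.close()
        if not seqs:
            raise ValueError("no sequences in FASTA input")
        return cls.from_strings(seqs)

    def write_fasta(self, target):
        recs = [
            SeqRecord(Seq("".join(BASES[c] if c < 4 else "N" for c in row)),
                      id=lbl, description="")
            for lbl, row in zip(self.labels, self.codes)
        ]
        if hasattr(target, "write"):
            SeqIO.write(recs, target, "fasta")
        else:
            with open(target, "w") as fh:
                SeqIO.write(recs, fh, "fasta")

    def patterns(self, order: list):
        """Compress columns into unique site patterns for the given
        row order; returns (patterns (npat, nseq), weights)."""
        idx = [self.labels.index(lbl) for lbl in order]
        cols = self.codes[idx].T  # (ncol, nseq)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq, counts.astype(np.float64)


class SubstitutionModel:
    """Time-reversible nucleotide model, normalised to unit rate."""

    def __init__(self, name="JC69", freqs=None, exchangeabilities=None):
        self.name = name
        self.freqs = (
            np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        )
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        if exchangeabilities is None:
            ex = np.ones((4, 4))
        else:
            ex = np.asarray(exchangeabilities, dtype=float)
        Q = ex * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise to one expected substitution per unit length
        scale = -(self.freqs * np.diag(Q)).sum()
        self.Q = Q / scale
        # reversible eigendecomposition via the symmetrised matrix
        sq = np.sqrt(self.freqs)
        S = (sq[:, None] * self.Q) / sq[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._L = U / sq[:, None] * 1.0
        self._R = (U * sq[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt)."""
        if self.name == "JC69":
            p = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            q = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
            M = np.full((4, 4), q)
            np.fill_diagonal(M, p)
            return M
        M = (self._L * np.exp(self._w * t)[None, :]) @ self._R
        return np.clip(M, 0.0, None)

    def transitions(self, lengths: np.ndarray) -> np.ndarray:
        return np.stack([self.transition(float(t)) for t in lengths])


def JC69() -> SubstitutionModel:
    return SubstitutionModel("JC69")


def leaf_partials(patterns: np.ndarray, ng: int, leaf_rows: dict) -> np.ndarray:
    """Initial conditional arrays: identity rows for observed bases,
    all-ones for missing data."""
    npat = patterns.shape[0]
    partials = np.zeros((ng, npat, 4))
    eye = np.vstack([np.eye(4), np.ones(4)])
    for v, row in leaf_rows.items():
        partials[v] = eye[patterns[:, row]]
    return partials


def peeling_likelihood(
    msa: MSA,
    gene: GeneTree,
    lengths: np.ndarray | None = None,
    model: SubstitutionModel | None = None,
) -> float:
    """log P(D | G, l) by postorder peeling with per-pattern rescaling."""
    model = model or JC69()
    lengths = gene.lengths if lengths is None else np.asarray(lengths, float)
    if np.any(lengths < 0):
        raise ValueError("negative edge length")
    leaf_ids = list(gene.leaves)
    order = [gene.labels[v] for v in leaf_ids]
    missing = set(order) - set(msa.labels)
    if missing:
        raise ValueError(f"no sequence for gene leaves: {sorted(missing)}")
    patterns, weights = msa.patterns(order)
    partials = leaf_partials(
        patterns, gene.n_vertices, {v: i for i, v in enumerate(leaf_ids)}
    )
    tprob = model.transitions(lengths)
    return float(
        _kernels.peeling(
            np.array(gene.postorder(), dtype=np.int64),
            gene.children,
            tprob,
            partials,
            weights,
            model.freqs,
            gene.root,
        )
    )
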