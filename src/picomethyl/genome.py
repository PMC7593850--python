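"""Genome ingest and cytosine-context site enumeration.

Bisulfite methylation calls are only interpretable relative to the catalog of
every assayable cytosine in the genome.  A cytosine's sequence context is read
in its own strand's 5'->3' direction: the two bases downstream classify it as
CpG (C followed by G), CHG (C-H-G) or CHH (C-H-H), where H is A, T or C.
Reverse-strand cytosines appear as G on the forward strand, with their
downstream bases lying at decreasing forward coordinates (complemented).

Coordinates are 0-based half-open throughout; GFF3 conversion happens only at
I/O boundaries.  Cytosines whose context window runs off the contig end or
touches an N cannot be assigned a context and are retained as ``ambiguous``
but excluded from per-context totals and downstream calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")
AMBIGUOUS = "ambiguous"

_VALID = frozenset(b"ACGTN")

# byte codes used by the vectorized classifier
_A, _C, _G, _T, _N = (ord(x) for x in "ACGTN")


class FastaError(ValueError):
    """Raised for malformed genome FASTA input."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{contig_id: uppercase sequence}``.

    Lowercase residues are normalized to uppercase; characters outside
    {A, C, G, T, N} and duplicate record ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such FASTA file: {path}")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - {"A", "C", "G", "T", "N"}
        if bad:
            raise FastaError(
                f"illegal residue(s) {sorted(bad)} in record {rec.id!r}"
            )
        genome[rec.id] = seq
    if not genome:
        raise FastaError(f"empty FASTA: {path}")
    return genome


def classify_context(residues: str, position: int, strand: str) -> str:
    """Classify one cytosine's sequence context.

    ``residues`` is the forward-strand contig sequence.  For ``strand == '-'``
    the base at ``position`` must be G (a cytosine on the reverse strand) and
    the context is read toward lower coordinates, complemented.
    """
    n = len(residues)
    if not 0 <= position < n:
        raise IndexError(f"position {position} outside contig of length {n}")
    base = residues[position]
    if strand == "+":
        if base != "C":
            raise ValueError(f"+ strand site at {position} is {base}, not C")
        window = residues[position + 1 : position + 3]
    elif strand == "-":
        if base != "G":
            raise ValueError(f"- strand site at {position} is {base}, not G")
        window = _revcomp(residues[max(position - 2, 0) : position])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    # CpG needs one downstream base; CHG/CHH need two.  N never matches H.
    if len(window) < 1 or window[0] == "N":
        return AMBIGUOUS
    if window[0] == "G":
        return "CpG"
    if len(window) < 2 or window[1] == "N":
        return AMBIGUOUS
    if window[1] == "G":
        return "CHG"
    return "CHH"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class SiteCatalog:
    """Every cytosine position on both strands with its context.

    ``sites`` has columns ``contig, pos, strand, context`` and is sorted by
    (contig, pos, strand).  ``context_totals`` counts non-ambiguous sites
    only; ``n_ambiguous`` tallies the excluded edge/N sites.
    """

    sites: pd.DataFrame
    context_totals: dict[str, int] = field(default_factory=dict)
    n_ambiguous: int = 0

    @property
    def n_sites(self) -> int:
        """Non-ambiguous site count."""
        return int(sum(self.context_totals.values()))

    def write_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteCatalog":
        df = pd.read_csv(
            path, sep="\t", dtype={"contig": str, "pos": np.int64, "strand": str, "context": str}
        )
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteCatalog":
        df = df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        nonamb = df[df["context"] != AMBIGUOUS]
        totals = {c: int((nonamb["context"] == c).sum()) for c in CONTEXTS}
        return cls(sites=df, context_totals=totals, n_ambiguous=int(len(df) - len(nonamb)))


def _classify_forward(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions and contexts of all forward-strand cytosines in a contig."""
    pos = np.flatnonzero(arr == _C)
    n = arr.size
    b1 = np.full(pos.size, _N, dtype=np.uint8)
    b2 = np.full(pos.size, _N, dtype=np.uint8)
    ok1 = pos + 1 < n
    ok2 = pos + 2 < n
    b1[ok1] = arr[pos[ok1] + 1]
    b2[ok2] = arr[pos[ok2] + 2]
    return pos, _context_codes(b1, b2, ok1, ok2)


def _classify_reverse(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions/contexts of reverse-strand cytosines (forward-strand Gs).

    The reverse strand reads 5'->3' toward lower forward coordinates, so the
    two downstream bases are the complements of ``arr[pos-1]`` and
    ``arr[pos-2]``.  Complementation maps CpG/CHG patterns onto forward-base
    tests: complement(x) == G iff x == C, complement(x) in H iff x in {T,A,G}.
    """
    pos = np.flatnonzero(arr == _G)
    comp = np.zeros(256, dtype=np.uint8)
    comp[[_A, _C, _G, _T, _N]] = [_T, _G, _C, _A, _N]
    b1 = np.full(pos.size, _N, dtype=np.uint8)
    b2 = np.full(pos.size, _N, dtype=np.uint8)
    ok1 = pos - 1 >= 0
    ok2 = pos - 2 >= 0
    b1[ok1] = comp[arr[pos[ok1] - 1]]
    b2[ok2] = comp[arr[pos[ok2] - 2]]
    return pos, _context_codes(b1, b2, ok1, ok2)


def _context_codes(
    b1: np.ndarray, b2: np.ndarray, ok1: np.ndarray, ok2: np.ndarray
) -> np.ndarray:
    """Map downstream base pairs to context labels (object array of str)."""
    out = np.full(b1.size, AMBIGUOUS, dtype=object)
    amb = ~ok1 | (b1 == _N)
    is_cpg = ~amb & (b1 == _G)
    h1 = ~amb & ~is_cpg  # b1 in {A,T,C}
    amb2 = h1 & (~ok2 | (b2 == _N))
    chg = h1 & ~amb2 & (b2 == _G)
    chh = h1 & ~amb2 & ~chg
    out[is_cpg] = "CpG"
    out[chg] = "CHG"
    out[chh] = "CHH"
    return out


def enumerate_sites(genome: dict[str, str]) -> SiteCatalog:
    """Enumerate every cytosine on both strands of every contig.

    Output order is (contig, pos, strand); per-context totals exclude
    ambiguous sites, which are retained in the frame but flagged.
    """
    if not genome:
        raise ValueError("empty genome")
    frames = []
    for contig in sorted(genome):
        arr = np.frombuffer(genome[contig].encode("ascii"), dtype=np.uint8)
        fpos, fctx = _classify_forward(arr)
        rpos, rctx = _classify_reverse(arr)
        pos = np.concatenate([fpos, rpos])
        strand = np.concatenate(
            [np.full(fpos.size, "+", dtype=object), np.full(rpos.size, "-", dtype=object)]
        )
        ctx = np.concatenate([fctx, rctx])
        frames.append(
            pd.DataFrame({"contig": contig, "pos": pos, "strand": strand, "context": ctx})
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contig", "pos", "strand", "context"]
    )
    catalog = SiteCatalog.from_frame(df)
    if catalog.n_ambiguous:
        log.info("excluded %d ambiguous sites (contig edge or N)", catalog.n_ambiguous)
    return catalog


def genome_site_fraction(catalog: SiteCatalog, genome_length: int) -> float:
    """Percent of the genome occupied by assayable cytosine sites.

    100 x (sum of non-ambiguous context totals) / genome_length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return 100.0 * catalog.n_sites / genome_length
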