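"""Genome handling and cytosine sequence-context classification.

Plant cytosine methylation is described in three sequence contexts — CG,
CHG and CHH, where H is A, C or T — read 5'->3' on the strand carrying the
cytosine.  This module loads a reference genome, classifies every cytosine
on both strands into its context, and summarizes context composition.

Coordinates are 0-based throughout the in-memory API; exported site tables
use 1-based positions (CX-report convention), BED/bedGraph exports are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
UNKNOWN = "UNKNOWN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named chromosome sequences plus a designated chloroplast.

    The chloroplast chromosome serves as the unmethylated internal control
    used to estimate bisulfite conversion efficiency.
    """

    sequences: dict[str, str]
    chloroplast_name: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome has no sequences")
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid bases: {sorted(bad)}")
            clean[name] = seq
        self.sequences = clean
        if self.chloroplast_name not in self.sequences:
            raise ValueError(
                f"chloroplast {self.chloroplast_name!r} not among chromosomes "
                f"{list(self.sequences)}"
            )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def nuclear_names(self) -> list[str]:
        return [c for c in self.sequences if c != self.chloroplast_name]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path, chloroplast_name: str) -> "Genome":
        """Read a (possibly line-wrapped, mixed-case) multi-record FASTA."""
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=sequences, chloroplast_name=chloroplast_name)

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        seqio_write(records, str(path), "fasta")


def classify_context(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at ``pos`` on ``strand``.

    A CG call needs only the next downstream base; CHG/CHH need two.  If the
    base required for the decision is missing (end of sequence) or N, the
    context is UNKNOWN.  Downstream of a reverse-strand cytosine runs toward
    lower forward coordinates, read as the complement.
    """
    seq = genome.sequences.get(chrom)
    if seq is None:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} out of range for {chrom} (len {len(seq)})")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        b1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        b2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]}, not C on the reverse strand")
        b1 = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else "N"
        b2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else "N"
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b1 == "N":
        return UNKNOWN
    if b1 == "G":
        return "CG"
    if b2 == "N":
        return UNKNOWN
    return "CHG" if b2 == "G" else "CHH"


def _strand_sites(seq_bytes: np.ndarray, reverse: bool) -> tuple[np.ndarray, np.ndarray]:
    """Positions and contexts of all cytosines on one strand (vectorized)."""
    n = seq_bytes.size
    if reverse:
        pos = np.flatnonzero(seq_bytes == ord("G"))
        # downstream bases on the reverse strand, already complemented:
        # forward C -> G, forward G -> C, A<->T, N stays N
        b1 = np.full(pos.size, ord("N"), dtype=np.uint8)
        b2 = np.full(pos.size, ord("N"), dtype=np.uint8)
        ok1 = pos - 1 >= 0
        ok2 = pos - 2 >= 0
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGTN", b"TGCAN"):
            comp[a] = b
        b1[ok1] = comp[seq_bytes[pos[ok1] - 1]]
        b2[ok2] = comp[seq_bytes[pos[ok2] - 2]]
    else:
        pos = np.flatnonzero(seq_bytes == ord("C"))
        b1 = np.full(pos.size, ord("N"), dtype=np.uint8)
        b2 = np.full(pos.size, ord("N"), dtype=np.uint8)
        ok1 = pos + 1 < n
        ok2 = pos + 2 < n
        b1[ok1] = seq_bytes[pos[ok1] + 1]
        b2[ok2] = seq_bytes[pos[ok2] + 2]
    ctx = np.full(pos.size, UNKNOWN, dtype=object)
    is_cg = b1 == ord("G")
    ctx[is_cg] = "CG"
    h1 = ~is_cg & (b1 != ord("N"))
    ctx[h1 & (b2 == ord("G"))] = "CHG"
    ctx[h1 & (b2 != ord("G")) & (b2 != ord("N"))] = "CHH"
    return pos, ctx


def enumerate_sites(genome: Genome) -> pd.DataFrame:
    """All strand-resolved cytosine sites of the genome with their contexts.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context,
    sorted by (chrom in genome order, pos, strand).  Symmetric CG pairs are
    kept strand-resolved (never merged).
    """
    frames = []
    for chrom, seq in genome.sequences.items():
        sb = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        fpos, fctx = _strand_sites(sb, reverse=False)
        rpos, rctx = _strand_sites(sb, reverse=True)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate([fpos, rpos]),
                "strand": np.concatenate(
                    [np.full(fpos.size, "+"), np.full(rpos.size, "-")]
                ),
                "context": np.concatenate([fctx, rctx]),
            }
        )
        df = df.sort_values(["pos", "strand"], kind="stable")
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


def context_frequencies(sites: pd.DataFrame) -> dict[str, int]:
    """Counts of sites per context; UNKNOWN reported separately."""
    counts = {c: 0 for c in CONTEXTS}
    counts[UNKNOWN] = 0
    if len(sites):
        vc = sites["context"].value_counts()
        for ctx, n in vc.items():
            counts[ctx] = int(n)
    return counts


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table with 1-based positions (CX-report style)."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sites["pos"] = sites["pos"].astype(np.int64) - 1
    return sites
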