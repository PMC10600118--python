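"""Plain-text sequence and feature I/O (FASTA, BED6, headered TSV).

All coordinates are 0-based half-open on the + strand of the reference,
matching BED convention.
"""

from __future__ import annotations

import hashlib
import io
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs to a FASTA file."""
    seqrecs = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_bed6(path: str | Path, rows: Iterable[tuple[str, int, int, str, int, str]]) -> None:
    """Write BED6 rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return rows


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr, for output provenance."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def tsv_header(version: str, seed=None, config=None) -> str:
    """Comment header echoed at the top of every tabular output file."""
    parts = [f"# delinver v{version}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts) + "\n# coordinates: 0-based half-open\n"


def write_tsv(path: str | Path, df, version: str, seed=None, config=None) -> None:
    """Write a DataFrame as TSV with the provenance comment header."""
    buf = io.StringIO()
    buf.write(tsv_header(version, seed=seed, config=config))
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
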