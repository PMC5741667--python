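"""Standard-format I/O: FASTA, BED6, TSV, PHYLIP, Newick, flat config."""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} preserving order (Python dicts do)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def write_bed6(path, rows: list[tuple]) -> None:
    """rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2]), f[3], int(float(f[4])), f[5]))
    return out


def write_newick(path, tree) -> None:
    Phylo.write(tree, str(path), "newick")


def newick_string(tree) -> str:
    buf = _io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def read_flat_config(path) -> dict[str, str]:
    """Flat ``key = value`` file; '#' starts a comment; keys unique."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {ln}: expected 'key = value', got '{line}'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key in out:
            raise ConfigError(f"duplicate key '{key}' (line {ln})")
        out[key] = value.strip()
    return out


def write_flat_config(path, values: dict) -> None:
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k} = {v}\n")
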