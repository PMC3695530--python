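"""Readers and writers for the plain-text genomic formats the pipeline uses.

BED is 0-based half-open; fixedStep wiggle is 1-based and converted to the
internal 0-based convention on ingest (and back on export). The gene
annotation dialect is a flat TSV: gene_id, chrom, strand, txStart, txEnd,
exonStarts, exonEnds (comma-separated), biotype.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .annotation import GeneModel
from .intervals import GenomicInterval


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- BED

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 records as GenomicInterval (name/score ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >=3 BED fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                _fail(path, lineno, f"bad strand {strand!r}")
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return out


def write_bed(path, records, track_name: str | None = None) -> None:
    """Write BED6 lines; records are GenomicInterval or (interval, name, score)."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track name="{track_name}" visibility=2\n')
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, name, score = rec, ".", 0
            else:
                iv, name, score = rec
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------- wiggle / bedGraph

def read_wiggle(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read bedGraph or fixedStep wiggle into {chrom: (positions, values)}.

    Positions are 0-based starts. bedGraph rows attach the value to the
    interval start; fixedStep declarations are 1-based and shifted by one.
    """
    pos: dict[str, list[int]] = {}
    val: dict[str, list[float]] = {}
    chrom, step, cursor = None, None, None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                try:
                    chrom = kv["chrom"]
                    cursor = int(kv["start"]) - 1  # 1-based -> 0-based
                    step = int(kv["step"])
                except (KeyError, ValueError):
                    _fail(path, lineno, "bad fixedStep declaration")
                continue
            if line.startswith("variableStep"):
                _fail(path, lineno, "variableStep wiggle not supported")
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 4:  # bedGraph row
                try:
                    c, s, v = fields[0], int(fields[1]), float(fields[3])
                except ValueError:
                    _fail(path, lineno, "malformed bedGraph row")
                pos.setdefault(c, []).append(s)
                val.setdefault(c, []).append(v)
            elif len(fields) == 1 and chrom is not None:
                try:
                    v = float(fields[0])
                except ValueError:
                    _fail(path, lineno, "malformed wiggle value")
                pos.setdefault(chrom, []).append(cursor)
                val.setdefault(chrom, []).append(v)
                cursor += step
            else:
                _fail(path, lineno, "unrecognized wiggle line")
    return {
        c: (np.array(pos[c], dtype=np.int64), np.array(val[c], dtype=float))
        for c in pos
    }


def write_bedgraph(path, tracks: dict, span: int = 1, track_name=None) -> None:
    """Write {chrom: (positions, values)} as bedGraph with fixed span."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, (positions, values) in tracks.items():
            for p, v in zip(positions, values):
                fh.write(f"{chrom}\t{p}\t{p + span}\t{v:g}\n")


def write_fixedstep_wiggle(path, tracks: dict, step: int, span=None) -> None:
    """Write {chrom: (start0, values)} as fixedStep wiggle (1-based on disk)."""
    span = span if span is not None else step
    with open(path, "w") as fh:
        for chrom, (start0, values) in tracks.items():
            fh.write(
                f"fixedStep chrom={chrom} start={int(start0) + 1} "
                f"step={step} span={span}\n"
            )
            for v in values:
                fh.write(f"{v:g}\n")


# ---------------------------------------------------------------- annotation dialect

_ANN_COLS = (
    "gene_id chrom strand txStart txEnd exonStarts exonEnds biotype".split()
)


def read_annotation(path) -> list[GeneModel]:
    """Read the flat gene-annotation TSV into GeneModel records."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_ANN_COLS):
                _fail(path, lineno, f"expected {len(_ANN_COLS)} columns")
            gid, chrom, strand, tx_s, tx_e, ex_s, ex_e, biotype = fields
            try:
                starts = [int(x) for x in ex_s.rstrip(",").split(",")]
                ends = [int(x) for x in ex_e.rstrip(",").split(",")]
                body = GenomicInterval(chrom, int(tx_s), int(tx_e), strand)
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(starts, ends, strict=True)
                )
                genes.append(GeneModel(gid, body, exons, biotype))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return genes


def write_annotation(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLS) + "\n")
        for g in genes:
            ex_s = ",".join(str(e.start) for e in g.exons)
            ex_e = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.strand}\t"
                f"{g.interval.start}\t{g.interval.end}\t{ex_s}\t{ex_e}\t{g.biotype}\n"
            )


# ---------------------------------------------------------------- chrom sizes

def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                _fail(path, lineno, "expected chrom<TAB>length")
            try:
                out[fields[0]] = int(fields[1])
            except ValueError:
                _fail(path, lineno, "non-integer length")
    return out


def write_chrom_sizes(path, lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, n in lengths.items():
            fh.write(f"{chrom}\t{n}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
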