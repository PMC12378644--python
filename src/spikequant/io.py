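"""Readers/writers shared by all pipeline stages.

TSV dialect: tab-separated, UTF-8, optional '#key=value' metadata header
lines before a single column-name line; missing values are empty
strings, never "NA". All writes are atomic (temp file + rename in the
target directory).
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matcher import Reference


class TsvFormatError(ValueError):
    """Malformed TSV; carries the 1-based offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_tsv(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    with atomic_write(path) as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline TSV, validating that every row has the header's
    column count; raises TsvFormatError naming the offending line."""
    meta_lines = 0
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if header is None:
                if line.startswith("#"):
                    meta_lines += 1
                    continue
                header = line.split("\t")
                if len(header) != len(set(header)):
                    raise TsvFormatError(path, line_no, "duplicate column names")
                continue
            if not line:
                continue
            n = line.count("\t") + 1
            if n != len(header):
                raise TsvFormatError(
                    path, line_no, f"expected {len(header)} columns, found {n}"
                )
    if header is None:
        raise TsvFormatError(path, 1, "no header line found")
    return pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, na_values=[""], **kwargs
    )


def read_tsv_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
    return meta


# ---------------------------------------------------------------------------
# FASTA / BED


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs; header may contain a description."""
    seq_records = []
    for header, seq in records:
        name, _, desc = header.partition(" ")
        seq_records.append(SeqRecord(Seq(seq), id=name, description=desc))
    with atomic_write(path) as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (full header, sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id if not rec.description or rec.description == rec.id else rec.description
        out.append((header, str(rec.seq)))
    return out


def write_reference_fasta(references: Iterable[Reference], path: str | Path) -> None:
    write_fasta(
        (
            (f"{r.ref_id} class={r.ref_class} group={r.group_id}", r.sequence)
            for r in references
        ),
        path,
    )


def read_reference_fasta(path: str | Path) -> list[Reference]:
    refs = []
    for header, seq in read_fasta(path):
        fields = header.split()
        attrs = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        if "class" not in attrs or "group" not in attrs:
            raise ValueError(
                f"{path}: reference {fields[0]!r} lacks class=/group= header attributes"
            )
        refs.append(Reference(fields[0], attrs["class"], attrs["group"], seq))
    return refs


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) as 4-column BED (0-based, half-open)."""
    with atomic_write(path) as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# config / manifest


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: Mapping[str, object] | None,
    seed: int | None,
    inputs: Iterable[str | Path] = (),
    outputs: Iterable[str | Path] = (),
    timestamp: str | None = None,
) -> dict:
    """Machine-readable run manifest; deterministic except 'timestamp'."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "python_version": sys.version.split()[0],
        "rng": "numpy.random.default_rng(PCG64)",
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "timestamp": timestamp,
    }
    with atomic_write(path) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
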