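"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: UTF-8 everywhere; TSV with mandatory headers for tabular data;
BED-style 0-based half-open coordinates in memory. One-based inputs (e.g.
bismark-style cytosine reports) are converted exactly once, at the reader
boundary, via ``read_cpg_report(..., one_based=True)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .equilibrium import LaneQuantification
from .methylome import CpgReport
from .motifs import GenomicInterval, MotifHit, Pwm
from .specseq import CountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_hits_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_cpg_report",
    "write_cpg_report",
    "read_lane_table",
    "read_count_table",
    "read_pwm",
    "write_pwm",
    "write_manifest",
]


def _fail(path: str | Path, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}:{lineno}: {msg}")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6; returns intervals (strand from column 6 when present)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                _fail(path, lineno, f"expected >= 3 BED columns, got {len(cols)}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates: {cols[1]!r}, {cols[2]!r}")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = f"{scores[i]:g}" if scores is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_hits_bed(path: str | Path, hits: Sequence[MotifHit]) -> None:
    write_bed(
        path,
        [h.interval for h in hits],
        names=[h.matched_sequence for h in hits],
        scores=[h.score for h in hits],
    )


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                _fail(path, lineno, "hits BED needs 6 columns")
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[5])
            hits.append(MotifHit(iv, float(cols[4]), cols[3]))
    return hits


def read_bedgraph(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """bedGraph to dense per-base arrays (small synthetic genomes only)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "value"],
        comment="t",  # skips optional 'track' header lines
        encoding="utf-8",
    )
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom"):
        L = lengths[chrom] if lengths else int(grp["end"].max())
        arr = np.zeros(L)
        for _, row in grp.iterrows():
            arr[int(row["start"]) : int(row["end"])] = row["value"]
        out[str(chrom)] = arr
    return out


def write_bedgraph(path: str | Path, track: Mapping[str, np.ndarray]) -> None:
    """Dense arrays to run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            edges = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_cpg_report(path: str | Path, one_based: bool = False) -> CpgReport:
    """TSV (chrom, position, count_methylated, count_unmethylated).

    Positions are 0-based in the file unless ``one_based=True`` (bismark
    convention), in which case they are shifted to 0-based on read.
    """
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    need = {"chrom", "position", "count_methylated", "count_unmethylated"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if one_based:
        df = df.assign(position=df["position"] - 1)
    return CpgReport(df)


def write_cpg_report(
    path: str | Path, report: CpgReport, one_based: bool = False
) -> None:
    df = report.table.copy()
    if one_based:
        df["position"] = df["position"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_lane_table(path: str | Path) -> list[LaneQuantification]:
    """TSV: lane_id, protein_total_nM, intensity_free, intensity_mon, intensity_dim."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    need = {"protein_total_nM", "intensity_free", "intensity_mon", "intensity_dim"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        LaneQuantification(
            row["intensity_free"],
            row["intensity_mon"],
            row["intensity_dim"],
            row["protein_total_nM"],
        )
        for _, row in df.iterrows()
    ]


def read_count_table(path: str | Path) -> CountTable:
    """TSV: sequence, count_input, count_monomer, count_dimer, condition."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    need = {"sequence", "count_input"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    condition = (
        str(df["condition"].iloc[0]) if "condition" in df.columns else "unmethylated"
    )
    counts = df.set_index("sequence").rename(
        columns={
            "count_input": "input",
            "count_monomer": "monomer",
            "count_dimer": "dimer",
        }
    )
    keep = [c for c in ("input", "monomer", "dimer") if c in counts.columns]
    return CountTable(counts[keep], condition=condition)


def read_pwm(path: str | Path) -> Pwm:
    """PWM text format: a '>name' header, then one tab-separated A C G T
    probability row per motif position."""
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        _fail(path, 1, "PWM file must start with a '>name' header")
    name = lines[0][1:].strip()
    rows = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != 4:
            _fail(path, lineno, f"expected 4 probabilities, got {len(vals)}")
        rows.append([float(v) for v in vals])
    return Pwm(name=name, matrix=np.array(rows))


def write_pwm(path: str | Path, pwm: Pwm) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{pwm.name}\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
    config: Mapping | None = None,
) -> Path:
    """Provenance record: version, config hash, seed, input checksums."""
    from . import __version__

    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    config_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "tool": "cpgpal",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "input_checksums": checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
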