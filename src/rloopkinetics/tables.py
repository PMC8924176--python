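"""Readers and writers: parameter files, measurement tables, FASTA, BED.

Parameter files are flat JSON objects; measurement tables are tab-separated
with a header, one row per measurement, patterns written as comma-joined
positions (empty for the on-target).  Both round-trip bit-exactly for
representable values (repr-precision floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .energy_model import MismatchPattern, ParameterSet
from .experiments import MeasurementRecord, QuantityKind
from .training import RawMeasurement

RAW_COLUMNS = ["sequence_id", "pattern", "kind", "log10_value", "log10_error",
               "physical"]
RECORD_COLUMNS = ["pattern", "kind", "log10_value", "log10_error"]


def read_parameter_file(path) -> ParameterSet:
    """Read a 44-parameter JSON file, validating counts and finiteness."""
    with open(path) as fh:
        data = json.load(fh)
    return ParameterSet.from_dict(data)


def write_parameter_file(path, params: ParameterSet) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
        fh.write("\n")


def _parse_rows(path, expected_columns):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(expected_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_raw_table(path) -> list[RawMeasurement]:
    """Read sequence-resolved measurements; malformed rows are reported with
    their line numbers and duplicate sequence ids per kind rejected."""
    df = _parse_rows(path, RAW_COLUMNS)
    rows: list[RawMeasurement] = []
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            key = (row["sequence_id"], row["kind"])
            if key in seen:
                raise ValueError(f"duplicate (sequence_id, kind) {key}")
            seen.add(key)
            QuantityKind(row["kind"])
            rows.append(RawMeasurement(
                sequence_id=row["sequence_id"],
                pattern=MismatchPattern.from_string(row["pattern"]),
                log10_value=float(row["log10_value"]),
                log10_error=float(row["log10_error"]),
                physical=row["physical"].strip().lower() in ("1", "true")))
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return rows


def write_raw_table(path, rows, kind: QuantityKind) -> None:
    df = pd.DataFrame({
        "sequence_id": [r.sequence_id for r in rows],
        "pattern": [r.pattern.to_string() for r in rows],
        "kind": [QuantityKind(kind).value] * len(rows),
        "log10_value": [repr(r.log10_value) for r in rows],
        "log10_error": [repr(r.log10_error) for r in rows],
        "physical": [str(r.physical).lower() for r in rows],
    })
    df.to_csv(path, sep="\t", index=False)


def read_record_table(path) -> list[MeasurementRecord]:
    """Read mismatch-averaged records (pattern, kind, log10 value/error)."""
    df = _parse_rows(path, RECORD_COLUMNS)
    records: list[MeasurementRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(MeasurementRecord(
                pattern=MismatchPattern.from_string(row["pattern"]),
                kind=QuantityKind(row["kind"]),
                log10_value=float(row["log10_value"]),
                log10_error=float(row["log10_error"])))
        except (ValueError, KeyError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return records


def write_record_table(path, records) -> None:
    df = pd.DataFrame({
        "pattern": [r.pattern.to_string() for r in records],
        "kind": [r.kind.value for r in records],
        "log10_value": [repr(r.log10_value) for r in records],
        "log10_error": [repr(r.log10_error) for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Contig name -> sequence (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_bed(path, sites, score_scale: float | None = None) -> None:
    """BED6 output (0-based half-open); BED scores scaled to 0-1000.

    Raw scores are preserved in a side TSV written next to the BED file
    (same stem, ``.scores.tsv``).
    """
    sites = list(sites)
    smax = max((s.score or 0.0) for s in sites) if sites else 1.0
    scale = score_scale if score_scale is not None else (1000.0 / smax if smax > 0 else 0.0)
    with open(path, "w") as fh:
        for s in sites:
            bed_score = int(round(min(1000.0, max(0.0, (s.score or 0.0) * scale))))
            name = s.pattern.to_string() or "on_target"
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{name}\t{bed_score}\t{s.strand}\n")
    side = Path(path).with_suffix(".scores.tsv")
    with open(side, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tpattern\tscore\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.strand}\t"
                     f"{s.pattern.to_string()}\t{repr(s.score) if s.score is not None else ''}\n")


def read_truth_sites(path) -> set:
    """Truth-set site keys from BED (first 6 cols) or contig:start-end:strand
    lines (1-based inclusive coordinates)."""
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                parts = line.split("\t")
                keys.add((parts[0], int(parts[1]), int(parts[2]),
                          parts[5] if len(parts) > 5 else "+"))
            else:
                loc, strand = line.rsplit(":", 1)
                contig, span = loc.rsplit(":", 1)
                lo, hi = span.split("-")
                keys.add((contig, int(lo) - 1, int(hi), strand))
    return keys
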