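"""Reading FASTA and writing profile tracks (WIG, bedGraph, TSV).

Coordinate conventions follow each format's native rules: WIG fixedStep
starts are 1-based, bedGraph intervals are 0-based half-open of width
``sample_step``, TSV positions are 1-based.  Writers are deterministic
byte-for-byte for identical inputs (no timestamps), and all paths support
transparent gzip by ``.gz`` extension.

Trained model statistics round-trip through a version-tagged JSON container
so conditional profiling can reuse a reference training pass.
"""

from __future__ import annotations

import gzip
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .engine import ProfileSamples
from .fcm import FcmModel

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "ModelFormatError",
    "read_fasta",
    "write_fasta",
    "write_wig",
    "read_wig",
    "write_bedgraph",
    "write_tsv",
    "read_tsv",
    "save_models",
    "load_models",
]

MODEL_FORMAT = "infoprofile-models"
MODEL_FORMAT_VERSION = 1


class FastaParseError(ValueError):
    """Input is not parseable FASTA."""


class ModelFormatError(ValueError):
    """Model container is missing, truncated, or of an unknown version."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: header token and upper-cased residues."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file into records, in file order.

    Residues are upper-cased; line wrapping and CRLF endings are tolerated.
    Raises :class:`FastaParseError` (with a line number where one can be
    attributed) for empty files or leading non-header content.
    """
    path = Path(path)
    with _open_text(path) as handle:
        # Biopython silently skips leading junk; report it with its line.
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {stripped[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: line 1: empty FASTA file")
        handle.seek(0)
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise FastaParseError(f"{path}: line 1: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA (gzip by extension)."""
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Track writers
# ---------------------------------------------------------------------------


def _fmt(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def write_wig(
    samples: ProfileSamples,
    path,
    track_name: str = "information_profile",
    decimals: int = 4,
) -> None:
    """Write samples as a UCSC ``wiggle_0`` custom track, fixedStep dialect.

    WIG has no missing-value record, so every run of masked (NaN) samples
    ends the current fixedStep block and a new block starts at the next
    valid sample.  ``step`` and ``span`` both equal the sampling step so
    each value covers its full sampling interval in the browser.  Samples
    not on a uniform ``step`` grid cannot be expressed as fixedStep; they
    fall back to a variableStep track with a warning.
    """
    step = samples.step
    pos_arr = np.asarray(samples.positions)
    uniform = pos_arr.size < 2 or bool((np.diff(pos_arr) == step).all())
    with _open_text(path, "wt") as out:
        out.write(f'track type=wiggle_0 name="{track_name}"\n')
        if not uniform:
            warnings.warn(
                f"{path}: samples are not on a uniform step-{step} grid; "
                "writing variableStep instead of fixedStep"
            )
            out.write(f"variableStep chrom={samples.sequence_id} span={step}\n")
            for pos, value in zip(samples.positions, samples.values):
                if not math.isnan(value):
                    out.write(f"{pos}\t{_fmt(value, decimals)}\n")
            return
        in_block = False
        for pos, value in zip(samples.positions, samples.values):
            if math.isnan(value):
                in_block = False
                continue
            if not in_block:
                out.write(
                    f"fixedStep chrom={samples.sequence_id} "
                    f"start={pos} step={step} span={step}\n"
                )
                in_block = True
            out.write(_fmt(value, decimals) + "\n")


def read_wig(path) -> ProfileSamples:
    """Parse a fixedStep WIG file written by :func:`write_wig`.

    Returns the samples with masked gaps restored as NaN on the common
    step grid.  Intended for round-tripping and downstream analysis of the
    tool's own tracks, not as a general-purpose WIG parser.
    """
    chrom = None
    step = None
    positions: list[int] = []
    values: list[float] = []
    with _open_text(path) as handle:
        pos = 0
        for line in handle:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"])
                step = int(fields.get("step", 1))
                continue
            if line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                step = int(fields.get("span", 1))
                pos = None
                continue
            parts = line.split()
            if pos is None:  # variableStep data line: position value
                positions.append(int(parts[0]))
                values.append(float(parts[1]))
            else:
                positions.append(pos)
                values.append(float(parts[0]))
                pos += step
    if chrom is None or step is None:
        raise ValueError(f"{path}: no fixedStep declaration line found")
    if not positions:
        return ProfileSamples(chrom, step, np.array([], int), np.array([], float))
    # restore NaN gaps on the full grid (only when samples sit on one)
    start, stop = positions[0], positions[-1]
    if any((p - start) % step for p in positions):
        return ProfileSamples(
            chrom, step, np.asarray(positions, int), np.asarray(values, float)
        )
    grid = np.arange(start, stop + 1, step)
    vals = np.full(grid.shape, np.nan)
    idx = (np.asarray(positions) - start) // step
    vals[idx] = values
    return ProfileSamples(chrom, step, grid, vals)


def write_bedgraph(
    samples: ProfileSamples,
    path,
    track_name: str = "information_profile",
    decimals: int = 4,
) -> None:
    """Write samples as bedGraph: 0-based half-open intervals of one step.

    A sample at 1-based position p covers ``[p-1, p-1+step)``; masked
    samples are simply omitted (bedGraph tolerates gaps natively).
    """
    step = samples.step
    with _open_text(path, "wt") as out:
        out.write(f'track type=bedGraph name="{track_name}"\n')
        for pos, value in zip(samples.positions, samples.values):
            if math.isnan(value):
                continue
            start = int(pos) - 1
            end = start + step
            if samples.sequence_length:
                end = min(end, samples.sequence_length)
            out.write(
                f"{samples.sequence_id}\t{start}\t{end}\t{_fmt(value, decimals)}\n"
            )


def write_tsv(samples: ProfileSamples, path, decimals: int = 4) -> None:
    """Tab-separated samples: sequence_id, position (1-based), info_bits, masked.

    Masked samples are kept as rows with an empty value and ``masked=1`` so
    the table covers the full sampling grid.
    """
    with _open_text(path, "wt") as out:
        out.write("sequence_id\tposition\tinfo_bits\tmasked\n")
        for pos, value in zip(samples.positions, samples.values):
            if math.isnan(value):
                out.write(f"{samples.sequence_id}\t{pos}\t\t1\n")
            else:
                out.write(
                    f"{samples.sequence_id}\t{pos}\t{_fmt(value, decimals)}\t0\n"
                )


def read_tsv(path) -> ProfileSamples:
    """Inverse of :func:`write_tsv` (masked rows become NaN)."""
    positions: list[int] = []
    values: list[float] = []
    seq_id = "seq"
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["sequence_id", "position"]:
            raise ValueError(f"{path}: not an information-profile TSV")
        for line in handle:
            sid, pos, val, masked = line.rstrip("\n").split("\t")
            seq_id = sid
            positions.append(int(pos))
            values.append(np.nan if masked == "1" or val == "" else float(val))
    step = positions[1] - positions[0] if len(positions) > 1 else 1
    return ProfileSamples(
        seq_id, step, np.asarray(positions, int), np.asarray(values, float)
    )


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


def save_models(
    models: Mapping[str, Sequence[FcmModel]] | Sequence[FcmModel], path
) -> None:
    """Serialize trained models losslessly to a JSON container.

    ``models`` is either a flat sequence or a mapping of named groups
    (conditional profiling stores one group per processing direction).
    Counts, orders and alphas round-trip exactly; gzip by extension.
    """
    if not isinstance(models, Mapping):
        models = {"default": list(models)}
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "groups": {
            name: [
                {
                    "order": m.order,
                    "alpha": m.alpha,
                    "contexts": [[ctx, *vec] for ctx, vec in m.iter_counts()],
                }
                for m in group
            ]
            for name, group in models.items()
        },
    }
    with _open_text(path, "wt") as out:
        json.dump(payload, out, separators=(",", ":"))
        out.write("\n")


def load_models(path) -> dict[str, list[FcmModel]]:
    """Load a model container written by :func:`save_models`.

    Raises :class:`ModelFormatError` on truncated files or on a container
    written by an incompatible version; no partially built models escape.
    """
    try:
        with _open_text(path) as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, EOFError, gzip.BadGzipFile) as exc:
        raise ModelFormatError(f"{path}: truncated or corrupt model container: {exc}")
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not an {MODEL_FORMAT} container")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: container version {payload.get('version')} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    groups: dict[str, list[FcmModel]] = {}
    for name, group in payload["groups"].items():
        models = []
        for entry in group:
            counts = {row[0]: row[1:5] for row in entry["contexts"]}
            models.append(FcmModel.from_counts(entry["order"], entry["alpha"], counts))
        groups[name] = models
    return groups
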