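"""Batch reading of sequence directories and writing of result bundles.

Input is a directory tree of FASTA/GenBank files, optionally gzip- or
zip-compressed; every file yields a list of :class:`SequenceRecord` with a
running per-file index (``seq_num``) so multi-record files stay
addressable.  Output mirrors the input hierarchy: each input file gets one
folder holding per-type site CSVs, optimized sequences in the requested
formats, a change summary, and a zip bundle, plus a joined multi-record
file next to the folder that matches the input file record-for-record.

Coordinates are 0-based half-open in memory and 1-based inclusive in all
CSV and report output (stated in the CSV headers).
"""

from __future__ import annotations

import gzip
import hashlib
import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "OutputBundle",
    "scan_input_directory",
    "read_records",
    "write_output_bundle",
    "sequence_identicon",
    "sites_to_table",
    "SITE_TABLE_COLUMNS",
]

FASTA = "FASTA"
GENBANK = "GENBANK"

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_GENBANK_EXT = {".gb", ".gbk", ".genbank"}
_ALLOWED = set("ACGTN")

SITE_TABLE_COLUMNS = [
    "seq_id",
    "seq_num",
    "type",
    "start_1based",
    "end_1based_inclusive",
    "length",
    "detail",
    "rate_or_score",
    "rank",
]


@dataclass
class SequenceRecord:
    """One DNA sequence with provenance and carried-through annotations."""

    id: str
    sequence: str
    source_path: str
    seq_num: int  # 1-based index within the source file
    features: list = field(default_factory=list)  # (label, start, end), 0-based half-open

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.seq_num < 1:
            raise ValueError("seq_num starts at 1")


@dataclass
class OutputBundle:
    """Everything written for one input file."""

    input_path: str  # relative to the scanned directory
    records: list  # original SequenceRecord list
    optimized_records: list  # SequenceRecord list (same ids/seq_nums)
    site_tables: dict  # type ("ssr"|"rmd"|"motif") -> DataFrame
    change_summary: list  # (seq_num, position_1based, old, new, reason)
    identicon_before: dict  # seq_num -> token
    identicon_after: dict
    report_lines: list = field(default_factory=list)


def sequence_identicon(sequence: str) -> str:
    """Deterministic short token identifying a sequence.

    Stands in for a graphical sequence icon: equal sequences map to equal
    tokens, and any single-base change flips the token with overwhelming
    probability (SHA-256 prefix).
    """
    if not sequence:
        raise ValueError("cannot fingerprint an empty sequence")
    digest = hashlib.sha256(sequence.upper().encode("ascii")).hexdigest()[:12]
    return f"{digest[:4]}-{digest[4:8]}-{digest[8:]}"


def _route_extension(name: str) -> str | None:
    suffixes = Path(name.lower()).suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if not suffixes:
        return None
    if suffixes[-1] in _FASTA_EXT:
        return FASTA
    if suffixes[-1] in _GENBANK_EXT:
        return GENBANK
    return None


def _sniff(text_head: str) -> str | None:
    stripped = text_head.lstrip()
    if stripped.startswith(">"):
        return FASTA
    if stripped.upper().startswith("LOCUS"):
        return GENBANK
    return None


def scan_input_directory(path: str | Path) -> list[tuple[str, str]]:
    """Find every sequence file under ``path``, with its inferred format.

    Returns ``(filepath, format)`` pairs; zip archives are expanded and
    each sequence member is listed as ``archive.zip!member``.  Files that
    are neither FASTA nor GenBank are skipped with a logged warning; an
    input tree with no sequence file at all is an error.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} does not exist")
    found: list[tuple[str, str]] = []
    for file in sorted(p for p in root.rglob("*") if p.is_file()):
        if file.suffix.lower() == ".zip":
            try:
                with zipfile.ZipFile(file) as archive:
                    for member in sorted(archive.namelist()):
                        tag = _route_extension(member)
                        if tag:
                            found.append((f"{file}!{member}", tag))
                        else:
                            logger.warning("skipping zip member %s!%s", file, member)
            except zipfile.BadZipFile:
                logger.warning("skipping unreadable zip %s", file)
            continue
        tag = _route_extension(file.name)
        if tag is None:
            try:
                head = _open_text(str(file)).read(200)
                tag = _sniff(head)
            except (OSError, UnicodeDecodeError):
                tag = None
        if tag:
            found.append((str(file), tag))
        else:
            logger.warning("skipping non-sequence file %s", file)
    if not found:
        raise FileNotFoundError(f"no input sequences found under {root}")
    return found


def _open_text(filepath: str) -> io.TextIOBase:
    if "!" in filepath:
        archive_path, member = filepath.split("!", 1)
        archive = zipfile.ZipFile(archive_path)
        return io.TextIOWrapper(archive.open(member))
    path = Path(filepath)
    if path.suffix.lower() == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_records(filepath: str, format_tag: str) -> list[SequenceRecord]:
    """Parse one file into :class:`SequenceRecord` s, seq_num assigned 1..n.

    Sequences are upper-cased; ``U`` is converted to ``T`` with a warning;
    ambiguity codes other than ``N`` are rejected (downstream editing
    semantics are undefined for them).  Malformed files raise — the batch
    driver records the error and continues with the remaining files.
    """
    fmt = "fasta" if format_tag == FASTA else "genbank"
    records: list[SequenceRecord] = []
    with _open_text(filepath) as handle:
        for seq_num, rec in enumerate(SeqIO.parse(handle, fmt), start=1):
            seq = str(rec.seq).upper()
            if "U" in seq:
                logger.warning("%s record %s: converting U to T", filepath, rec.id)
                seq = seq.replace("U", "T")
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(
                    f"{filepath} record {rec.id}: unsupported ambiguity codes "
                    f"{sorted(bad)} (only A,C,G,T,N accepted)"
                )
            features = []
            for feature in getattr(rec, "features", []):
                if feature.location is not None:
                    features.append(
                        (feature.type, int(feature.location.start), int(feature.location.end))
                    )
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=seq,
                    source_path=filepath,
                    seq_num=seq_num,
                    features=features,
                )
            )
    if not records:
        raise ValueError(f"{filepath}: no records parsed")
    return records


def sites_to_table(record: SequenceRecord, site_type: str, sites: list) -> pd.DataFrame:
    """Flatten detected sites into the CSV site-table schema (1-based spans)."""
    rows = []
    for rank, site in enumerate(sites, start=1):
        if site_type == "ssr":
            start, end = site.start, site.end
            detail = f"unit={site.unit};N={site.n_copies}"
        elif site_type == "rmd":
            start, end = site.first_start, site.second_start + site.repeat_len
            detail = (
                f"repeat_len={site.repeat_len};spacer={site.spacer};"
                f"second_start_1based={site.second_start + 1}"
            )
        else:
            start, end = site.start, site.end
            detail = f"motif={site.motif};strand={site.strand}"
        rows.append(
            {
                "seq_id": record.id,
                "seq_num": record.seq_num,
                "type": site_type,
                "start_1based": start + 1,
                "end_1based_inclusive": end,
                "length": end - start,
                "detail": detail,
                "rate_or_score": site.rate_or_score,
                "rank": rank,
            }
        )
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def _to_seqrecord(record: SequenceRecord, changes: list | None = None) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        description="",
        annotations={"molecule_type": "DNA"},
    )
    for label, start, end in record.features:
        rec.features.append(SeqFeature(FeatureLocation(start, end), type=label[:15] or "misc_feature"))
    for seq_num, pos_1based, old, new, reason in changes or []:
        if seq_num != record.seq_num:
            continue
        feat = SeqFeature(FeatureLocation(pos_1based - 1, pos_1based), type="misc_feature")
        feat.qualifiers["label"] = [f"{old}>{new} ({reason})"]
        rec.features.append(feat)
    return rec


def _versioned(path: Path) -> Path:
    if not path.exists():
        return path
    version = 1
    while True:
        candidate = path.with_name(f"{path.name}.v{version}")
        if not candidate.exists():
            logger.warning("output %s exists; writing to %s", path, candidate)
            return candidate
        version += 1


def write_output_bundle(
    bundle: OutputBundle,
    outdir: str | Path,
    formats: set[str] = frozenset({FASTA}),
    make_zip: bool = True,
    include_sequences: bool = True,
) -> list[Path]:
    """Write one bundle's folder (and joined file) under ``outdir``.

    The folder sits at the input file's relative location so the output
    tree mirrors the input tree; a name collision gets a versioned suffix.
    ``include_sequences=False`` (report-only runs) writes the site tables
    and summary but no sequence files.  Returns the list of written paths.
    """
    outdir = Path(outdir)
    rel = Path(bundle.input_path)
    stem = rel.name.split(".")[0]
    folder = _versioned(outdir / rel.parent / stem)
    folder.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    header_note = "# coordinates are 1-based inclusive\n"
    for site_type in ("ssr", "rmd", "motif"):
        table = bundle.site_tables.get(site_type, pd.DataFrame(columns=SITE_TABLE_COLUMNS))
        path = folder / f"sites_{site_type}.csv"
        with open(path, "w") as handle:
            handle.write(header_note)
            table.to_csv(handle, index=False)
        written.append(path)

    seq_records = [_to_seqrecord(r, bundle.change_summary) for r in bundle.optimized_records]
    if not include_sequences:
        formats = set()
        make_zip = False
    if FASTA in formats:
        path = folder / "optimized.fasta"
        SeqIO.write(seq_records, path, "fasta")
        written.append(path)
    if GENBANK in formats:
        path = folder / "optimized.gb"
        SeqIO.write(seq_records, path, "genbank")
        written.append(path)

    summary = folder / "summary.txt"
    with open(summary, "w") as handle:
        handle.write(f"input: {bundle.input_path}\n")
        for record in bundle.optimized_records:
            num = record.seq_num
            handle.write(
                f"seq {num} ({record.id}): identicon {bundle.identicon_before.get(num)}"
                f" -> {bundle.identicon_after.get(num)}\n"
            )
        handle.write("changes (position is 1-based):\n")
        for seq_num, pos, old, new, reason in bundle.change_summary:
            handle.write(f"  seq {seq_num} pos {pos}: {old}>{new} {reason}\n")
        for line in bundle.report_lines:
            handle.write(f"note: {line}\n")
    written.append(summary)

    if include_sequences:
        # joined multi-record file matching the input file
        joined = _versioned(outdir / rel.parent / f"{stem}_optimized.fasta")
        SeqIO.write(seq_records, joined, "fasta")
        written.append(joined)

    if make_zip:
        zip_path = folder / "bundle.zip"
        with zipfile.ZipFile(zip_path, "w") as archive:
            gb_text = io.StringIO()
            SeqIO.write(seq_records, gb_text, "genbank")
            archive.writestr("final.gb", gb_text.getvalue())
            archive.writestr("report.txt", summary.read_text())
            tokens = "\n".join(
                f"{num}\t{tok}" for num, tok in sorted(bundle.identicon_after.items())
            )
            archive.writestr("identicon.txt", tokens + "\n")
        written.append(zip_path)
    return written
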