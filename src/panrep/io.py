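"""File formats and configuration.

FASTQ here is the strict 4-line-per-record layout produced by Illumina
basecallers; the reader tracks line numbers so malformed or truncated
records are reported at the offending line (which is why it is not a thin
wrapper over a generic parser).  FASTA goes through Biopython.  Gzip is
transparent for any path ending in ``.gz``.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence, Union

import yaml

from .amplicon import Read

__all__ = [
    "open_text",
    "read_fastq",
    "write_fastq",
    "read_fastq_pair",
    "write_fastq_pair",
    "read_fasta",
    "write_fasta",
    "PipelineConfig",
    "load_config",
    "dump_config",
]

PathLike = Union[str, Path]


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield reads from a 4-line FASTQ file, raising on malformed records
    with the 1-based line number of the problem."""
    with open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not seq:
                raise ValueError(f"{path}: line {lineno + 1}: truncated record")
            if not plus:
                raise ValueError(f"{path}: line {lineno + 2}: truncated record")
            if not plus.startswith("+"):
                raise ValueError(f"{path}: line {lineno + 2}: expected '+' separator")
            if not qual:
                raise ValueError(f"{path}: line {lineno + 3}: truncated record")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            lineno += 3
            yield Read(header[1:].strip(), seq, qual)


def write_fastq(path: PathLike, reads: Iterable[Read]) -> int:
    n = 0
    with open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def read_fastq_pair(path1: PathLike, path2: PathLike) -> Iterator[tuple[Read, Read]]:
    """Iterate synchronized read pairs from _R1/_R2 files."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise ValueError(f"{path2}: fewer reads than {path1}")
        yield r1, r2
    if next(it2, None) is not None:
        raise ValueError(f"{path2}: more reads than {path1}")


def write_fastq_pair(
    path1: PathLike, path2: PathLike, pairs: Iterable[tuple[Read, Read]]
) -> int:
    n = 0
    with open_text(path1, "wt") as f1, open_text(path2, "wt") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.id}\n{r1.seq}\n+\n{r1.qual}\n")
            f2.write(f"@{r2.id}\n{r2.seq}\n+\n{r2.qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping; duplicate ids error."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
            out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: PathLike, records: Mapping[str, str], width: int = 70) -> int:
    with open_text(path, "wt") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return len(records)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MergeParams:
    min_overlap: int = 20
    max_mismatch_rate: float = 0.05


@dataclasses.dataclass
class FilterParams:
    # band bounds sized to the simulator's amplicon geometry (457-580 nt);
    # set 550/850 -- the gel-cut band length_filter defaults to -- for real
    # PE300 data (see docs/methods.md)
    min_len: int = 450
    max_len: int = 850
    min_mean_q: float = 20.0


@dataclasses.dataclass
class AnnotateParams:
    max_primer_mismatches: int = 2
    max_fr_mismatches: int = 3


@dataclasses.dataclass
class EnrichParams:
    pseudocount: float = 0.5
    min_late_count: int = 2
    min_ratio: float = 1.0
    selectivity_mode: str = "share"


@dataclasses.dataclass
class SimulateParams:
    """Subset of SimulationConfig exposed in the pipeline config file."""

    n_clones: int = 5000
    n_binders_per_subtype: int = 20
    reads_per_sample: int = 4500
    n_replicates: int = 3
    n_rounds: int = 4
    seq_error_rate: float = 1e-4
    amplification_noise_sd: float = 0.3
    capture_scale: float = 1e-3
    shared_binders: bool = False


@dataclasses.dataclass
class PipelineConfig:
    """Resolved end-to-end run configuration.

    ``simulate=True`` generates inputs with the synthetic module; otherwise
    ``samples`` must list dicts with keys r1, r2, round, subtype, replicate
    (and optional tumor_model/tissue) pointing at paired FASTQ files.
    """

    seed: int = 0
    simulate: bool = True
    key_level: str = "full_aa"
    outdir: str = "panrep_out"
    write_fastq: bool = False
    samples: list = dataclasses.field(default_factory=list)
    simulation: SimulateParams = dataclasses.field(default_factory=SimulateParams)
    merge: MergeParams = dataclasses.field(default_factory=MergeParams)
    filter: FilterParams = dataclasses.field(default_factory=FilterParams)
    annotate: AnnotateParams = dataclasses.field(default_factory=AnnotateParams)
    enrich: EnrichParams = dataclasses.field(default_factory=EnrichParams)


_SECTIONS = {
    "simulation": SimulateParams,
    "merge": MergeParams,
    "filter": FilterParams,
    "annotate": AnnotateParams,
    "enrich": EnrichParams,
}


def _from_mapping(cls, data: Mapping, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: Mapping) -> PipelineConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _from_mapping(cls, data.pop(name) or {}, name)
    top = _from_mapping(PipelineConfig, {**data, **{k: None for k in kwargs}}, "pipeline")
    for k, v in kwargs.items():
        setattr(top, k, v)
    for name, cls in _SECTIONS.items():
        if getattr(top, name) is None:
            setattr(top, name, cls())
    return top


def load_config(path: PathLike) -> PipelineConfig:
    with open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: PathLike) -> None:
    """Write the fully resolved configuration beside the outputs."""
    with open_text(path, "wt") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------


def annotations_to_frame(records) -> "pandas.DataFrame":
    """Annotated VHH records as a tidy table (one row per read).

    Region intervals are 0-based half-open on the amino-acid sequence.
    """
    import pandas as pd

    from .amplicon import REGION_ORDER

    rows = []
    for r in records:
        row = {
            "read_id": r.read_id,
            "complete": r.complete,
            "nt_cds": r.nt_cds,
            "aa": r.aa_sequence,
        }
        for name in REGION_ORDER:
            if name in r.regions:
                s, e = r.regions[name]
                row[f"{name.lower()}_aa"] = r.aa_sequence[s:e]
                row[f"{name.lower()}_start"] = s
                row[f"{name.lower()}_end"] = e
        if r.regions:
            row["full_aa"] = r.full_aa
            row["cdr3_nt"] = r.region_nt("CDR3")
        rows.append(row)
    return pd.DataFrame(rows)


def write_clonotypes(table, path: PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_clonotypes(path: PathLike):
    """Load a clonotype TSV written by :func:`write_clonotypes`."""
    import pandas as pd

    from .repertoire import ClonotypeTable, SampleMeta

    df = pd.read_csv(path, sep="\t", dtype={"key": str})
    if df.empty:
        raise ValueError(f"{path}: empty clonotype table")
    first = df.iloc[0]
    repl = first.get("replicate")
    meta = SampleMeta(
        tumor_model=str(first.get("tumor_model", "") or ""),
        tissue=str(first.get("tissue", "") or ""),
        subtype=str(first.get("subtype", "") or ""),
        round=int(first.get("round", 0)),
        replicate=None if pd.isna(repl) else int(repl),
    )
    counts = df.set_index("key")["count"]
    return ClonotypeTable(counts, str(first["key_level"]), meta)


def write_json(obj, path: PathLike) -> None:
    with open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
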