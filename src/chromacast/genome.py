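"""Genome ingestion: FASTA reading, base encoding, chunking, blacklists and the
HDF5 training container.

A genome is tiled into fixed-length windows ("chunks") on both strands. Bases
are encoded as 4-dimensional vectors in the fixed channel order ``C, A, T, G``
(a single source of truth, :data:`CHANNEL_ORDER`); the ambiguity code ``N``
becomes the uniform vector ``[0.25, 0.25, 0.25, 0.25]`` so it stays
distinguishable from padding, which is the all-zero vector. Only terminal
chunks carry padding. With this channel order, reverse complementation is a
simultaneous reversal of the position and channel axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
from Bio import SeqIO

from chromacast.errors import DataError

#: Fixed channel order of the 4-dimensional base encoding.
CHANNEL_ORDER = "CATG"

#: Schema version written to / required from the HDF5 container.
CONTAINER_SCHEMA = "chromacast-container-1"

_ENCODING = {
    "C": (1.0, 0.0, 0.0, 0.0),
    "A": (0.0, 1.0, 0.0, 0.0),
    "T": (0.0, 0.0, 1.0, 0.0),
    "G": (0.0, 0.0, 0.0, 1.0),
    "N": (0.25, 0.25, 0.25, 0.25),
}

# byte-indexed lookup table; row 5 flags an illegal character
_LUT = np.zeros((256, 4), dtype=np.float64)
_LEGAL = np.zeros(256, dtype=bool)
for _res, _vec in _ENCODING.items():
    for _b in (ord(_res), ord(_res.lower())):
        _LUT[_b] = _vec
        _LEGAL[_b] = True


@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record: an assembly sequence (chromosome, scaffold, contig)."""

    seq_id: str
    length: int
    residues: str

    def __post_init__(self) -> None:
        if self.length != len(self.residues):
            raise DataError(
                f"sequence {self.seq_id!r}: length field {self.length} does not "
                f"match {len(self.residues)} residues"
            )


@dataclass
class EncodedChunk:
    """One fixed-length, strand-specific window of encoded sequence.

    ``start``/``end`` are 0-based half-open coordinates on the plus strand,
    regardless of ``strand``; a minus-strand chunk stores the reverse
    complement of the same window, with positions running 3'→5' relative to
    the plus strand. ``pad_mask`` is ``True`` at real bases and ``False`` at
    padded positions (all-zero rows). ``is_gap`` flags chunks whose real bases
    are all ``N``; those carry no usable sequence signal.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    matrix: np.ndarray
    pad_mask: np.ndarray
    is_gap: bool


@dataclass(frozen=True)
class Blacklist:
    """Set of flagged sequence IDs (unplaced scaffolds, organellar genomes)."""

    seq_ids: frozenset[str] = field(default_factory=frozenset)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.seq_ids

    def __len__(self) -> int:
        return len(self.seq_ids)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased; record order is preserved. Duplicate headers and
    empty files raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith((">", ";")):
            raise DataError(f"{path}: line 1 is not a FASTA header: {first.strip()!r}")
        handle.seek(0)
        records = [
            GenomeSequence(rec.id, len(rec.seq), str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.seq_id in seen:
            raise DataError(f"{path}: duplicate sequence ID {rec.seq_id!r}")
        seen.add(rec.seq_id)
    return records


def encode_base(residue: str) -> np.ndarray:
    """Encode one residue as its 4-vector in channel order ``C,A,T,G``.

    ``N`` maps to the uniform vector. Padding positions are not bases and are
    represented by ``[0, 0, 0, 0]`` (see :func:`chunk_genome`).
    """
    if len(residue) != 1:
        raise DataError(f"expected a single residue, got {residue!r}")
    vec = _ENCODING.get(residue.upper())
    if vec is None:
        raise DataError(f"cannot encode residue {residue!r}; expected one of A,C,G,T,N")
    return np.array(vec, dtype=np.float64)


def encode_sequence(residues: str) -> np.ndarray:
    """Vectorised encoding of a residue string to an ``(L, 4)`` matrix."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = ~_LEGAL[raw]
    if bad.any():
        idx = int(np.argmax(bad))
        raise DataError(
            f"cannot encode residue {residues[idx]!r} at position {idx}; "
            "expected one of A,C,G,T,N"
        )
    return _LUT[raw].copy()


def reverse_complement_matrix(matrix: np.ndarray) -> np.ndarray:
    """Reverse complement an encoded matrix.

    In the ``C,A,T,G`` channel order the complement (C↔G, A↔T) is exactly the
    reversal of the channel axis, so the operation is ``matrix[::-1, ::-1]``.
    Padding rows (all zeros) and ``N`` rows (uniform) are fixed points of the
    channel flip.
    """
    return matrix[::-1, ::-1].copy()


def chunk_genome(seq: GenomeSequence, L: int, strand: str = "+") -> list[EncodedChunk]:
    """Cut one sequence into consecutive, non-overlapping ``L``-bp chunks.

    Chunks tile ``[0, seq.length)``; only the terminal chunk may contain
    padding (zero rows, ``pad_mask`` False). Minus-strand chunks carry the
    reverse complement with positions reversed, so their padding sits at the
    chunk start.
    """
    if L <= 0:
        raise ValueError(f"chunk length must be positive, got {L}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    encoded = encode_sequence(seq.residues)
    is_n = np.all(encoded == 0.25, axis=1)
    chunks: list[EncodedChunk] = []
    for start in range(0, seq.length, L):
        end = min(start + L, seq.length)
        n_real = end - start
        matrix = np.zeros((L, 4), dtype=np.float64)
        matrix[:n_real] = encoded[start:end]
        pad_mask = np.zeros(L, dtype=bool)
        pad_mask[:n_real] = True
        is_gap = bool(np.all(is_n[start:end]))
        if strand == "-":
            matrix = reverse_complement_matrix(matrix)
            pad_mask = pad_mask[::-1].copy()
        chunks.append(EncodedChunk(seq.seq_id, start, end, strand, matrix, pad_mask, is_gap))
    return chunks


def filter_chunks(
    chunks: Iterable[EncodedChunk], blacklist: Blacklist, drop_gaps: bool = True
) -> list[EncodedChunk]:
    """Drop chunks from blacklisted sequences and, optionally, gap chunks.

    Relative order is preserved.
    """
    return [
        c
        for c in chunks
        if c.seq_id not in blacklist and not (drop_gaps and c.is_gap)
    ]


def load_blacklist(path: str | Path) -> Blacklist:
    """Load flagged sequence IDs from a plain ID list or a JSON-lines report.

    JSON-lines records are assembly sequence reports: any record whose role or
    placement marks it as organellar (mitochondrion/chloroplast/plastid) or as
    an unplaced/unlocalized scaffold contributes its sequence name.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"blacklist file not found: {path}")
    ids: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("{"):
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise DataError(f"{path}:{lineno}: unparseable JSON line: {exc}") from exc
                seq_id = _flagged_seq_id(record)
                if seq_id is not None:
                    ids.add(seq_id)
            else:
                if any(ch.isspace() for ch in line):
                    raise DataError(
                        f"{path}:{lineno}: expected one sequence ID per line, got {line!r}"
                    )
                ids.add(line)
    return Blacklist(frozenset(ids))


def _flagged_seq_id(record: dict) -> str | None:
    """Return the record's sequence name if it is flagged, else None."""
    name = (
        record.get("sequence_name")
        or record.get("seq_id")
        or record.get("genbank_accession")
        or record.get("refseq_accession")
    )
    if name is None:
        raise DataError(f"JSON record carries no sequence-name field: {record!r}")
    role = str(record.get("role", "")).lower()
    assigned = str(record.get("assigned_molecule_location_type", "")).lower()
    placement = str(record.get("assembly_unit", "")).lower()
    non_nuclear = assigned in ("mitochondrion", "chloroplast", "plastid") or "non-nuclear" in placement
    unplaced = "unplaced" in role or "unlocalized" in role or "unplaced" in placement
    return str(name) if (non_nuclear or unplaced) else None


# ---------------------------------------------------------------------------
# HDF5 container


def write_container(
    path: str | Path,
    genome: Sequence[GenomeSequence],
    chunks: Sequence[EncodedChunk],
    tracks: dict[str, np.ndarray] | None = None,
    blacklist: Blacklist | None = None,
    config_hash: str | None = None,
) -> None:
    """Persist encoded chunks (and optional per-chunk coverage) as HDF5.

    ``tracks`` maps a dataset name (e.g. ``"atac"``) to an ``(n_chunks, L)``
    float array aligned with ``chunks``; padded positions should carry the
    sentinel ``-1`` (they are excluded through ``pad_mask`` downstream).
    The container without a coverage group is valid prediction-only input.
    """
    chunks = list(chunks)
    if not chunks:
        raise DataError("refusing to write a container with zero chunks")
    L = chunks[0].matrix.shape[0]
    blacklist = blacklist or Blacklist()
    if tracks:
        for name, arr in tracks.items():
            if arr.shape != (len(chunks), L):
                raise DataError(
                    f"coverage track {name!r} has shape {arr.shape}, "
                    f"expected {(len(chunks), L)}"
                )
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CONTAINER_SCHEMA
        f.attrs["subseq_len"] = L
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        grp = f.create_group("data")
        grp.create_dataset(
            "X", data=np.stack([c.matrix for c in chunks]).astype(np.float32)
        )
        grp.create_dataset("pad_mask", data=np.stack([c.pad_mask for c in chunks]))
        grp.create_dataset("is_gap", data=np.array([c.is_gap for c in chunks]))
        grp.create_dataset(
            "blacklist", data=np.array([c.seq_id in blacklist for c in chunks])
        )
        grp.create_dataset("seq_id", data=[c.seq_id for c in chunks], dtype=str_dt)
        grp.create_dataset("start", data=np.array([c.start for c in chunks], dtype=np.int64))
        grp.create_dataset("end", data=np.array([c.end for c in chunks], dtype=np.int64))
        grp.create_dataset("strand", data=[c.strand for c in chunks], dtype=str_dt)
        g = f.create_group("genome")
        g.create_dataset("seq_id", data=[s.seq_id for s in genome], dtype=str_dt)
        g.create_dataset("length", data=np.array([s.length for s in genome], dtype=np.int64))
        if tracks:
            cov = f.create_group("coverage")
            for name, arr in tracks.items():
                cov.create_dataset(name, data=arr.astype(np.float32))


@dataclass
class Container:
    """In-memory view of the HDF5 training container."""

    subseq_len: int
    chunks: list[EncodedChunk]
    blacklist_flags: np.ndarray
    seq_lengths: dict[str, int]
    tracks: dict[str, np.ndarray]

    @property
    def prediction_only(self) -> bool:
        return not self.tracks


def read_container(path: str | Path) -> Container:
    """Read a container written by :func:`write_container`.

    A missing coverage group yields a prediction-only container; a wrong or
    missing schema version raises :class:`DataError`.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DataError(f"cannot read container {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != CONTAINER_SCHEMA:
            raise DataError(
                f"{path}: container schema {version!r} does not match "
                f"expected {CONTAINER_SCHEMA!r}"
            )
        grp = f["data"]
        X = grp["X"][...].astype(np.float64)
        pad = grp["pad_mask"][...]
        gaps = grp["is_gap"][...]
        bl = grp["blacklist"][...]
        seq_ids = [s.decode() if isinstance(s, bytes) else s for s in grp["seq_id"][...]]
        starts = grp["start"][...]
        ends = grp["end"][...]
        strands = [s.decode() if isinstance(s, bytes) else s for s in grp["strand"][...]]
        chunks = [
            EncodedChunk(seq_ids[i], int(starts[i]), int(ends[i]), strands[i],
                         X[i], pad[i], bool(gaps[i]))
            for i in range(len(seq_ids))
        ]
        g = f["genome"]
        names = [s.decode() if isinstance(s, bytes) else s for s in g["seq_id"][...]]
        lengths = dict(zip(names, (int(x) for x in g["length"][...])))
        tracks: dict[str, np.ndarray] = {}
        if "coverage" in f:
            for name, ds in f["coverage"].items():
                tracks[name] = ds[...].astype(np.float64)
        subseq_len = int(f.attrs["subseq_len"])
    return Container(subseq_len, chunks, bl, lengths, tracks)
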