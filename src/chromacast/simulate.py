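"""Synthetic genomes and coverage with known ground truth.

The generator emulates, at desk scale, the geometry seen around plant
transcription-start sites: a planted motif acts as a TSS-like anchor driving a
narrow ATAC-like accessibility peak centred on the motif, flanked by a broader
H3K4me3-like peak shifted downstream. Observed per-base counts are Poisson
samples of the expected rate (low uniform background plus truncated-Gaussian
bumps). Everything downstream — chunking, containers, training, evaluation —
can be exercised against these tracks with exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from chromacast.coverage import CoverageTrack, track_to_chunks
from chromacast.errors import ConfigError, DataError
from chromacast.genome import Blacklist, GenomeSequence, chunk_genome, write_container
from chromacast.peaks import Peak, PeakCallParams, call_peaks

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of one synthetic dataset.

    Defaults are sized for a single CPU: 64 sequences × 8192 bp with 1024-bp
    subsequences. The 12-bp motif makes chance exact matches negligible
    (≈0.03 expected per default genome). Peak height is the added expected
    rate at the bump maximum, in reads/bp over the uniform background.
    """

    n_sequences: int = 64
    seq_length: int = 8192
    motif: str = "TGACGTCATGCA"
    n_sites: int = 4
    atac_peak_width: int = 200
    chip_peak_width: int = 600
    chip_offset: int = 300
    peak_height: float = 6.0
    background_rate: float = 0.25
    subseq_len: int = 1024
    seed: int = 0

    def validate(self) -> None:
        if not set(self.motif) <= set("ACGT"):
            raise ConfigError(f"motif must be over ACGT, got {self.motif!r}")
        if max(self.atac_peak_width, self.chip_peak_width) >= self.seq_length:
            raise ConfigError("peak widths must be smaller than the sequence length")
        if not self.peak_height > self.background_rate >= 0:
            raise ConfigError("need peak_height > background_rate ≥ 0")
        if self.seq_length % self.subseq_len:
            raise ConfigError("seq_length must be a multiple of subseq_len")


@dataclass(frozen=True)
class Site:
    """One planted motif instance; ``position`` is the motif start (0-based)."""

    seq_id: str
    position: int
    strand: str

    def center(self, motif_len: int) -> int:
        return self.position + motif_len // 2


def generate_genome(spec: SyntheticSpec) -> tuple[list[GenomeSequence], list[Site]]:
    """I.i.d. uniform ACGT background with the motif planted at non-overlapping
    random positions (random strand); reproducible given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    margin = spec.chip_offset + spec.chip_peak_width // 2 + len(spec.motif)
    min_sep = len(spec.motif) + max(spec.atac_peak_width, spec.chip_peak_width)
    lo, hi = margin, spec.seq_length - margin - len(spec.motif)
    if spec.n_sites > 0 and (hi <= lo or (hi - lo) < spec.n_sites * min_sep):
        raise ConfigError(
            f"cannot place {spec.n_sites} non-overlapping sites in "
            f"[{lo}, {hi}) with separation {min_sep}"
        )
    sequences: list[GenomeSequence] = []
    sites: list[Site] = []
    bases = np.array(list("ACGT"))
    for i in range(spec.n_sequences):
        seq_id = f"seq{i:03d}"
        residues = rng.choice(bases, size=spec.seq_length)
        positions: list[int] = []
        attempts = 0
        while len(positions) < spec.n_sites:
            attempts += 1
            if attempts > 1000 * max(spec.n_sites, 1):
                raise DataError("failed to place non-overlapping motif sites")
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - p) >= min_sep for p in positions):
                positions.append(pos)
        for pos in sorted(positions):
            strand = "+" if rng.random() < 0.5 else "-"
            motif = spec.motif if strand == "+" else spec.motif.translate(_COMPLEMENT)[::-1]
            residues[pos: pos + len(motif)] = list(motif)
            sites.append(Site(seq_id, pos, strand))
        sequences.append(GenomeSequence(seq_id, spec.seq_length, "".join(residues)))
    return sequences, sites


def bump_profile(length: int, center: int, width: int, height: float) -> np.ndarray:
    """A truncated-Gaussian bump: σ = width/4, support |offset| ≤ 2σ, maximum
    ``height`` at the centre."""
    sigma = width / 4.0
    offsets = np.arange(length) - center
    bump = height * np.exp(-0.5 * (offsets / sigma) ** 2)
    bump[np.abs(offsets) > 2 * sigma] = 0.0
    return bump


def expected_rates(
    spec: SyntheticSpec, sites: list[Site]
) -> dict[str, dict[str, np.ndarray]]:
    """Noise-free expected coverage per sequence and dataset kind.

    ATAC bumps centre on the motif; ChIP bumps sit ``chip_offset`` bp
    downstream (strand-aware) with their own width.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    by_seq: dict[str, list[Site]] = {}
    for site in sites:
        by_seq.setdefault(site.seq_id, []).append(site)
    for seq_id in sorted({s.seq_id for s in sites}):
        atac = np.full(spec.seq_length, spec.background_rate)
        chip = np.full(spec.seq_length, spec.background_rate)
        for site in by_seq.get(seq_id, []):
            center = site.center(len(spec.motif))
            sign = 1 if site.strand == "+" else -1
            atac += bump_profile(spec.seq_length, center,
                                 spec.atac_peak_width, spec.peak_height)
            chip += bump_profile(spec.seq_length, center + sign * spec.chip_offset,
                                 spec.chip_peak_width, spec.peak_height)
        out[seq_id] = {"atac": atac, "chip": chip}
    return out


def generate_coverage(
    genome: list[GenomeSequence], sites: list[Site], spec: SyntheticSpec
) -> tuple[dict[str, dict[str, CoverageTrack]], dict[str, dict[str, np.ndarray]]]:
    """Poisson-sample observed tracks from the expected rates.

    Returns ``(observed, expected)``: observed maps seq_id → kind →
    :class:`CoverageTrack` of integer counts; expected carries the noise-free
    rate arrays (the simulator's ground truth).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)  # independent of sequence draws
    rates = expected_rates(spec, sites) if sites else {}
    observed: dict[str, dict[str, CoverageTrack]] = {}
    expected: dict[str, dict[str, np.ndarray]] = {}
    for seq in genome:
        seq_rates = rates.get(
            seq.seq_id,
            {"atac": np.full(spec.seq_length, spec.background_rate),
             "chip": np.full(spec.seq_length, spec.background_rate)},
        )
        expected[seq.seq_id] = seq_rates
        observed[seq.seq_id] = {
            kind: CoverageTrack(seq.seq_id, kind,
                                rng.poisson(rate).astype(np.float64))
            for kind, rate in seq_rates.items()
        }
    return observed, expected


def truth_peaks(spec: SyntheticSpec, sites: list[Site]) -> dict[str, list[Peak]]:
    """Ground-truth peak intervals per dataset kind, from the noise-free
    expected rates thresholded midway between background and peak maximum."""
    cutoff = spec.background_rate + 0.5 * spec.peak_height
    rates = expected_rates(spec, sites)
    params = PeakCallParams(cutoff=cutoff, min_length=10, max_gap=10)
    peaks: dict[str, list[Peak]] = {"atac": [], "chip": []}
    for seq_id in sorted(rates):
        for kind in ("atac", "chip"):
            peaks[kind].extend(call_peaks(rates[seq_id][kind], params, seq_id))
    return peaks


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic dataset: FASTA, bedGraph tracks, truth-peak BEDs,
    site annotations and the HDF5 training container.

    Everything downstream consumes only these files. Returns the paths keyed
    by artefact name.
    """
    from chromacast.cli_io import write_bed, write_bedgraph, write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, sites = generate_genome(spec)
    observed, _ = generate_coverage(genome, sites, spec)
    paths: dict[str, Path] = {}

    paths["fasta"] = out_dir / "genome.fa"
    write_fasta(genome, paths["fasta"])

    for kind in ("atac", "chip"):
        paths[f"{kind}_bedgraph"] = out_dir / f"{kind}.bedgraph"
        write_bedgraph({s.seq_id: observed[s.seq_id][kind] for s in genome},
                       paths[f"{kind}_bedgraph"])
    truths = truth_peaks(spec, sites)
    for kind in ("atac", "chip"):
        paths[f"{kind}_truth_bed"] = out_dir / f"truth_{kind}.bed"
        write_bed(truths[kind], paths[f"{kind}_truth_bed"])
    paths["sites_bed"] = out_dir / "sites.bed"
    write_bed(
        [Peak(s.seq_id, s.position, s.position + len(spec.motif), 1.0) for s in sites],
        paths["sites_bed"],
        strands=[s.strand for s in sites],
    )

    # both-strand chunks + per-chunk coverage targets → container
    all_chunks = []
    tracks: dict[str, list[np.ndarray]] = {"atac": [], "chip": []}
    for seq in genome:
        for strand in ("+", "-"):
            chunks = chunk_genome(seq, spec.subseq_len, strand)
            all_chunks.extend(chunks)
            for kind in ("atac", "chip"):
                tracks[kind].append(track_to_chunks(observed[seq.seq_id][kind], chunks))
    stacked = {kind: np.concatenate(arrs) for kind, arrs in tracks.items()}
    paths["container"] = out_dir / "data.h5"
    from chromacast.cli_io import config_hash

    write_container(paths["container"], genome, all_chunks, stacked, Blacklist(),
                    config_hash=config_hash(spec))

    paths["spec_json"] = out_dir / "spec.json"
    paths["spec_json"].write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return paths
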