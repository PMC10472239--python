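"""Packaged synthetic reference genome.

A fixed-seed random two-chromosome genome (2 Mb total) used for self-contained
SBS96/ID83 classification, variant simulation and CIN-window tests. The
sequence is generated at import-call time from a hard-coded seed rather than
shipped as a file, so it is always bit-identical across installs.
"""

from __future__ import annotations

import functools
from pathlib import Path

import numpy as np

_GENOME_SEED = 20240917
CHROM_SIZES = {"chr1": 1_200_000, "chr2": 800_000}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@functools.lru_cache(maxsize=1)
def synthetic_genome() -> dict[str, str]:
    """Return the packaged synthetic genome as {chrom: sequence}.

    Uniform random bases seeded with implanted homopolymer runs and short
    tandem-repeat arrays (microsatellite-like), so that every homopolymer /
    repeat-context indel channel has realizable sites — a purely iid
    sequence would essentially lack long repeat arrays.
    """
    rng = np.random.default_rng(_GENOME_SEED)
    genome = {}
    for chrom, size in CHROM_SIZES.items():
        arr = _BASES[rng.integers(0, 4, size=size)].copy()
        n_implants = size // 400
        for _ in range(n_implants):
            pos = int(rng.integers(50, size - 100))
            if rng.random() < 0.5:      # homopolymer run, 4-12 bases
                base = _BASES[rng.integers(0, 4)]
                run = int(rng.integers(4, 13))
                arr[pos:pos + run] = base
            else:                        # tandem array: 2-6 bp unit, 2-8 copies
                unit_len = int(rng.integers(2, 7))
                copies = int(rng.integers(2, 9))
                unit = _BASES[rng.integers(0, 4, size=unit_len)]
                tile = np.tile(unit, copies)
                arr[pos:pos + tile.size] = tile
        genome[chrom] = arr.tobytes().decode("ascii")
    return genome


def write_fasta(path: str | Path, genome: dict[str, str] | None = None,
                width: int = 80) -> Path:
    """Write the genome to ``path`` as FASTA (one record per chromosome)."""
    genome = genome if genome is not None else synthetic_genome()
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def tile_windows(window_size: int = 50_000,
                 genome: dict[str, str] | None = None) -> list[tuple[str, int, int]]:
    """Tile the genome into half-open 0-based windows of ``window_size`` bp.

    A shorter trailing window is emitted when a chromosome length is not a
    multiple of the window size.
    """
    genome = genome if genome is not None else synthetic_genome()
    windows = []
    for chrom, seq in genome.items():
        n = len(seq)
        for start in range(0, n, window_size):
            windows.append((chrom, start, min(start + window_size, n)))
    return windows
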