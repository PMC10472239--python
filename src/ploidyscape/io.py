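"""Format plumbing: 16-bit images, FASTA, VCF, signature TSVs, BED windows.

Readers delegate to the standard libraries (tifffile / imageio, pyfaidx,
pysam, pandas); the VCF writer emits minimal standard-conformant VCF 4.2
text that round-trips through pysam.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pysam
import tifffile

from .signatures import SignatureMatrix, VariantRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# images

def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 16-bit TIFF/PNG; label images round-trip.

    8-bit input is promoted to uint16 with a warning; RGB or float images
    are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:
        raise ValueError("multi-channel (RGB) images are not supported; "
                         "supply one single-channel file per stain")
    if img.dtype == np.uint8:
        warnings.warn("8-bit image promoted to 16-bit", stacklevel=2)
        return img.astype(np.uint16)
    if img.dtype in (np.uint16, np.int32):
        return img
    raise ValueError(f"unsupported image dtype {img.dtype}; expected uint8/uint16")


def write_image(path: str | Path, image: np.ndarray) -> Path:
    path = Path(path)
    image = np.asarray(image)
    if image.dtype not in (np.uint16, np.int32):
        if np.issubdtype(image.dtype, np.integer) and image.max() <= 65535 \
                and image.min() >= 0:
            image = image.astype(np.uint16)
        else:
            raise ValueError("only 16-bit (or int32 label) images are written")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# sequences and variants

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into {contig: sequence} (via pyfaidx)."""
    import pyfaidx
    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic records from a VCF 4.x file (via pysam)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                out.append(VariantRecord(chrom=rec.chrom, pos=rec.pos,
                                         ref=rec.ref, alt=alt))
    return out


def write_vcf(path: str | Path, variants, contigs: dict[str, int]) -> Path:
    """Write a minimal VCF 4.2 file (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if isinstance(v, VariantRecord):
                chrom, pos, ref, alt = v.chrom, v.pos, v.ref, v.alt
            else:
                chrom, pos, ref, alt = v
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
    return path


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    return [VariantRecord(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# tables

def read_signature_tsv(path: str | Path) -> SignatureMatrix:
    """Signature TSV: first column channel labels, one column per signature."""
    return SignatureMatrix.from_tsv(path)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3 windows (half-open, 0-based)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BED coordinates") from exc
    return rows


def write_catalog_tsv(path: str | Path, labels, counts,
                      sample_id: str = "sample") -> Path:
    path = Path(path)
    pd.DataFrame({"channel": list(labels), sample_id: np.asarray(counts)}) \
        .to_csv(path, sep="\t", index=False)
    return path
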