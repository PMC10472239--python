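"""Simulated mutation catalogs from known signature-exposure mixtures.

Catalog counts are multinomial draws from the mixture distribution
``signature_matrix @ exposures``; an optional FFPE forward model adds
C>T-dominated artifact counts on top of the biological catalog, which is
exactly what the correction stage must undo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..signatures import SignatureMatrix


@dataclass(frozen=True)
class CatalogSimConfig:
    """Configuration for one simulated catalog.

    ``exposures`` are relative contributions (non-negative, sum to 1) over
    the columns of ``signatures``; ``n_mutations`` is the biological total;
    ``ffpe_artifact_fraction`` is the fraction of the *final* catalog made
    of artifact counts.
    """
    signatures: SignatureMatrix
    exposures: tuple[float, ...]
    n_mutations: int
    ffpe_artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        e = np.asarray(self.exposures, dtype=float)
        if e.size != len(self.signatures.names):
            raise ValueError("exposure length does not match signature count")
        if (e < 0).any() or abs(e.sum() - 1.0) > 1e-9:
            raise ValueError("exposures must be non-negative and sum to 1 "
                             "(tol 1e-9)")
        if not 0.0 <= self.ffpe_artifact_fraction < 1.0:
            raise ValueError("ffpe_artifact_fraction must lie in [0, 1)")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be non-negative")


def simulate_catalog(config: CatalogSimConfig) -> np.ndarray:
    """Draw channel counts: multinomial(n_mutations, S @ e)."""
    e = np.asarray(config.exposures, dtype=float)
    p = config.signatures.matrix @ e
    p = p / p.sum()
    rng = np.random.default_rng(config.seed)
    return rng.multinomial(config.n_mutations, p).astype(np.int64)


def add_ffpe_artifacts(counts: np.ndarray, artifact_profile: np.ndarray,
                       fraction: float, seed: int = 0) -> np.ndarray:
    """Overlay multinomial FFPE artifact counts on a biological catalog.

    The artifact total is chosen so that it makes up ``fraction`` of the
    output catalog: artifact = round(fraction * output_total). Biological
    counts are left untouched.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("artifact fraction must lie in [0, 1)")
    counts = np.asarray(counts, dtype=np.int64)
    profile = np.asarray(artifact_profile, dtype=np.float64)
    if profile.shape != counts.shape:
        raise ValueError("artifact profile and catalog schemas differ")
    if fraction == 0.0:
        return counts.copy()
    total = int(counts.sum())
    n_artifact = int(round(fraction * total / (1.0 - fraction)))
    rng = np.random.default_rng(seed)
    return counts + rng.multinomial(n_artifact, profile / profile.sum())
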