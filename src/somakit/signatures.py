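"""Trinucleotide-context handling and mutational-signature refitting.

SNVs are classed into the conventional 96 pyrimidine-centred trinucleotide
substitution contexts.  Refitting decomposes a sample's 96-bin count vector
as a non-negative mixture of signature profiles (non-negative least squares);
the residual is the L1 distance between observed and fitted counts.
Signatures contributing <5% of a sample's fitted load or fewer than 300
variants are excluded from the reported set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = ["CONTEXTS", "context_index", "context_label", "SignatureFit",
           "fit_signatures", "random_signature_matrix"]

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: The 96 context labels, ordered by substitution class then 5'/3' flanks.
CONTEXTS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBS for five in _BASES for three in _BASES
)

_INDEX = {c: i for i, c in enumerate(CONTEXTS)}


def context_index(label: str) -> int:
    return _INDEX[label]


def context_label(i: int) -> str:
    return CONTEXTS[i]


def context_of(five: str, ref: str, alt: str, three: str) -> str:
    """Label for an SNV given its flanks; purine refs are strand-folded."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref in "AG":
        ref, alt = comp[ref], comp[alt]
        five, three = comp[three], comp[five]
    return f"{five}[{ref}>{alt}]{three}"


def random_signature_matrix(n_signatures: int = 30, seed: int = 0,
                            concentration: float = 0.05) -> np.ndarray:
    """Synthetic signature matrix (96 x n), columns non-negative, sum 1.

    A sparse-Dirichlet stand-in for a curated signature catalogue: low
    concentration yields well-separated, peaky profiles, which is what the
    refitting tests need.
    """
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    return mat / mat.sum(axis=0, keepdims=True)


@dataclass
class SignatureFit:
    contributions: np.ndarray       # fitted variant load per signature
    residual: float                 # sum |observed - fitted| over 96 bins
    reported: dict[str, float]      # name -> load, after exclusion filters
    names: tuple[str, ...]

    @property
    def total(self) -> float:
        return float(self.contributions.sum())


def fit_signatures(counts: np.ndarray, signatures: np.ndarray,
                   names: tuple[str, ...] | None = None,
                   min_fraction: float = 0.05,
                   min_load: float = 300.0) -> SignatureFit:
    """Refit a 96-context count vector onto signature profiles.

    Parameters
    ----------
    counts : (96,) non-negative SNV counts per context.
    signatures : (96, k) column-normalised signature profiles.
    min_fraction, min_load : reporting filters; a signature is excluded from
        the reported set when its contribution is below 5% of the sample
        total or its absolute fitted load is below 300 variants (strict).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("counts must have shape (96,)")
    if np.any(counts < 0):
        raise ValueError("negative context counts")
    if signatures.shape[0] != 96:
        raise ValueError("signature matrix must have 96 rows")
    k = signatures.shape[1]
    names = names or tuple(f"S{i + 1}" for i in range(k))
    coef, _ = nnls(signatures, counts)
    fitted = signatures @ coef
    residual = float(np.abs(counts - fitted).sum())
    total = coef.sum()
    reported = {}
    tol = 1e-6  # NNLS solutions sit within ~1e-10 of the true loads
    for name, load in zip(names, coef):
        if (total > 0 and load / total >= min_fraction - tol
                and load >= min_load - tol):
            reported[name] = float(load)
    return SignatureFit(coef, residual, reported, tuple(names))


def counts_from_contexts(labels) -> np.ndarray:
    """96-bin count vector from an iterable of context labels."""
    counts = np.zeros(96)
    for lab in labels:
        if lab is not None:
            counts[_INDEX[lab]] += 1
    return counts
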