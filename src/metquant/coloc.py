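"""Cytoplasm-restricted, single-direction Manders colocalization.

M1 is the fraction of cytoplasmic DNA signal residing in protein-positive
pixels.  The nuclear signal is removed from both channels first, because the
question is whether *cytoplasmic* DNA sits in protein-marked compartments;
and only the DNA→protein direction is computed by default, because control
cells have essentially no cytoplasmic DNA, which makes the reverse
coefficient meaningless there.

With per-channel thresholds t_dna and t_protein and nuclear pixels removed:

    M1 = Σ DNA_i over {i : DNA_i > t_dna and protein_i > t_protein}
         ─────────────────────────────────────────────────────────
         Σ DNA_i over {i : DNA_i > t_dna}

Setting t_dna = 0 reproduces the unthresholded denominator variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from metquant.segment import mask_exclude


class NoCytoplasmicDNAError(ValueError):
    """No DNA-positive cytoplasmic pixel: M1 is undefined (the control-cell
    situation), signalled explicitly rather than leaked as 0/0."""


@dataclass
class ColocResult:
    m1: float
    t_dna: float
    t_protein: float
    n_pixels_dna_positive: int
    coloc_map: np.ndarray       # joint-positive cytoplasmic pixels
    m2: float | None = None     # protein→DNA direction, opt-in only


def _resolve_thresholds(
    dna: np.ndarray,
    protein: np.ndarray,
    thresholds: tuple[float, float] | None,
) -> tuple[float, float]:
    if thresholds is not None:
        return float(thresholds[0]), float(thresholds[1])
    out = []
    for img in (dna, protein):
        out.append(float(threshold_otsu(img)) if np.ptp(img) > 0 else float(img.max()))
    return out[0], out[1]


def manders_cytoplasmic(
    dna: np.ndarray,
    protein: np.ndarray,
    nuclear_mask: np.ndarray,
    thresholds: tuple[float, float] | None = None,
    compute_m2: bool = False,
) -> ColocResult:
    """Compute cytoplasmic M1 (DNA→protein) on a single registered slice.

    ``thresholds`` is ``(t_dna, t_protein)``; when None, Otsu is applied per
    channel after nuclear removal.  Raises :class:`NoCytoplasmicDNAError`
    when no cytoplasmic pixel exceeds the DNA threshold.
    """
    dna = np.asarray(dna, dtype=np.float64)
    protein = np.asarray(protein, dtype=np.float64)
    if dna.shape != protein.shape:
        raise ValueError(f"shape mismatch: dna {dna.shape} vs protein {protein.shape}")
    dna_c = mask_exclude(dna, nuclear_mask)
    prot_c = mask_exclude(protein, nuclear_mask)
    t_dna, t_protein = _resolve_thresholds(dna_c, prot_c, thresholds)
    dna_pos = dna_c > t_dna
    denom = float(dna_c[dna_pos].sum())
    n_dna = int(dna_pos.sum())
    if n_dna == 0 or denom == 0:
        raise NoCytoplasmicDNAError(
            "no DNA-positive cytoplasmic pixel above threshold; M1 is undefined"
        )
    joint = dna_pos & (prot_c > t_protein)
    m1 = float(dna_c[joint].sum()) / denom
    m2 = None
    if compute_m2:
        prot_pos = prot_c > t_protein
        denom2 = float(prot_c[prot_pos].sum())
        m2 = float(prot_c[joint].sum()) / denom2 if denom2 > 0 else float("nan")
    return ColocResult(m1, t_dna, t_protein, n_dna, joint, m2)


def coloc_map(
    dna: np.ndarray,
    protein: np.ndarray,
    nuclear_mask: np.ndarray,
    thresholds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Binary map of joint-positive cytoplasmic pixels (the M1 numerator
    support); usable as a colocalization highlighter overlay."""
    dna = np.asarray(dna, dtype=np.float64)
    protein = np.asarray(protein, dtype=np.float64)
    if dna.shape != protein.shape:
        raise ValueError(f"shape mismatch: dna {dna.shape} vs protein {protein.shape}")
    dna_c = mask_exclude(dna, nuclear_mask)
    prot_c = mask_exclude(protein, nuclear_mask)
    t_dna, t_protein = _resolve_thresholds(dna_c, prot_c, thresholds)
    return (dna_c > t_dna) & (prot_c > t_protein)
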