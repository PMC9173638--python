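"""XIP peptide variants, proteolytic cleavage products and monoisotopic
[M+H]+ m/z prediction.

The salivarius pheromone XIP (LPYFAGCL) is cleaved by the oligo-
endopeptidase PepF after residues 4 (Phe) and 5 (Ala), releasing the
N-terminal fragments LPYF and LPYFA that are observed by LC-MS.  Masses
are monoisotopic with free N- and C-termini, reduced cysteine and charge
+1 — the conventions that reproduce the observed singly protonated peaks.

Note on reporting: observed m/z values in chromatogram annotations are
conventionally written with trailing digits dropped rather than rounded
(883.4382 appears as 883.43); :func:`mz_printed` applies that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "Peptide",
    "CleavageProduct",
    "PeakAssignment",
    "XIP",
    "cleave",
    "mz_mh",
    "mz_printed",
    "match_peaks",
    "apply_substitutions",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of a proton (Da).
PROTON = 1.007276466621
#: Monoisotopic mass of water (Da).
WATER = 18.0105646863


@dataclass(frozen=True)
class Peptide:
    """A peptide over the 20 standard one-letter amino-acid codes."""

    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence is empty")
        bad = [c for c in self.sequence if c not in _AA]
        if bad:
            raise ValueError(f"invalid residue code(s): {bad!r}")

    def __len__(self) -> int:
        return len(self.sequence)


#: The native S. salivarius pheromone.
XIP = Peptide("LPYFAGCL", label="XIP")

#: PepF cleavage positions on XIP (bond cut after these residues).
XIP_CLEAVAGE_SITES = (4, 5)


@dataclass(frozen=True)
class CleavageProduct:
    """A fragment of a parent peptide with its span and predicted m/z."""

    fragment: Peptide
    span: tuple[int, int]  # 1-based inclusive positions within the parent
    predicted_mz: float  # monoisotopic [M+H]+, Da
    terminus: Literal["N-terminal", "C-terminal", "intact"]


def mz_mh(peptide: Peptide | str) -> float:
    """Monoisotopic [M+H]+ m/z (Da) of a peptide.

    Sum of monoisotopic residue masses plus one water (free termini) and
    one proton (charge +1); cysteines as free thiols.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else Peptide(peptide).sequence
    return float(_pmass.calculate_mass(sequence=seq, ion_type="M", charge=1))


def mz_printed(mz: float, decimals: int = 2) -> float:
    """Truncate an m/z value to the given number of decimals.

    Chromatogram annotations drop trailing digits rather than rounding;
    this reproduces that reporting convention.
    """
    scale = 10**decimals
    return math.floor(mz * scale) / scale


def cleave(
    parent: Peptide | str, sites: Sequence[int] = XIP_CLEAVAGE_SITES
) -> list[CleavageProduct]:
    """Enumerate cleavage products for cuts after the given 1-based positions.

    Each site yields an N-terminal and a complementary C-terminal product
    whose concatenation restores the parent.  The intact parent is always
    included (it is the dominant species without enzyme, and the reference
    peak in spectra).  An empty site list yields the parent only.
    """
    if isinstance(parent, str):
        parent = Peptide(parent)
    n = len(parent)
    products = [
        CleavageProduct(
            fragment=parent,
            span=(1, n),
            predicted_mz=mz_mh(parent),
            terminus="intact",
        )
    ]
    for k in sites:
        if not (1 <= k < n):
            raise ValueError(f"cleavage site {k} outside 1..{n - 1}")
        nt = Peptide(parent.sequence[:k], label=f"{parent.label or parent.sequence}[1-{k}]")
        ct = Peptide(
            parent.sequence[k:], label=f"{parent.label or parent.sequence}[{k + 1}-{n}]"
        )
        products.append(
            CleavageProduct(nt, (1, k), mz_mh(nt), "N-terminal")
        )
        products.append(
            CleavageProduct(ct, (k + 1, n), mz_mh(ct), "C-terminal")
        )
    return products


@dataclass(frozen=True)
class PeakAssignment:
    observed_mz: float
    product: CleavageProduct | None
    ppm_error: float | None


def match_peaks(
    observed: Iterable[float],
    candidates: Sequence[CleavageProduct],
    tolerance_ppm: float = 20.0,
) -> list[PeakAssignment]:
    """Assign observed peaks to the closest candidate within tolerance.

    Ties (identical predicted m/z) are broken toward the longer fragment.
    Unmatched peaks are returned with a ``None`` product.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    out = []
    for mz in observed:
        best = None
        best_err = None
        for cand in candidates:
            err = abs(mz - cand.predicted_mz) / cand.predicted_mz * 1e6
            if err > tolerance_ppm:
                continue
            if (
                best is None
                or err < best_err - 1e-12
                or (abs(err - best_err) <= 1e-12 and len(cand.fragment) > len(best.fragment))
            ):
                best, best_err = cand, err
        signed = None
        if best is not None:
            signed = (mz - best.predicted_mz) / best.predicted_mz * 1e6
        out.append(PeakAssignment(observed_mz=mz, product=best, ppm_error=signed))
    return out


def apply_substitutions(parent: Peptide | str, substitutions: Sequence[str]) -> Peptide:
    """Apply point substitutions written like ``F4W`` (original, position, new).

    The stated original residue must match the parent at that 1-based
    position; mismatches are rejected to guard against off-by-one errors.
    Substitutions are applied in order, each validated against the current
    sequence (so ``F4W`` then ``A5I`` on LPYFAGCL gives LPYWIGCL).
    """
    if isinstance(parent, str):
        parent = Peptide(parent)
    seq = list(parent.sequence)
    applied = []
    for sub in substitutions:
        if len(sub) < 3:
            raise ValueError(f"malformed substitution {sub!r}")
        orig, new = sub[0], sub[-1]
        try:
            pos = int(sub[1:-1])
        except ValueError:
            raise ValueError(f"malformed substitution {sub!r}") from None
        if orig not in _AA or new not in _AA:
            raise ValueError(f"invalid residue code in {sub!r}")
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {pos} outside 1..{len(seq)} in {sub!r}")
        if seq[pos - 1] != orig:
            raise ValueError(
                f"substitution {sub!r}: position {pos} is {seq[pos - 1]}, not {orig}"
            )
        seq[pos - 1] = new
        applied.append(sub)
    label = parent.label or parent.sequence
    if applied:
        label = f"{label}_{'-'.join(applied)}"
    return Peptide("".join(seq), label=label)
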