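"""The 304-measure dysphonia battery: manifest, ordering, extraction.

Families and counts: jitter 28, shimmer 21, hnr_nhr 4, gq 3, gne 6, vfer 9,
emd_er 6, mfcc 39, f0_related 3, wavelet 182, ppe 1, dfa 1, rpde 1 = 304.
The name/order manifest is frozen: feature columns are identified by name,
never by insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import FeatureFlagged, Phonation, PhonoscreenError
from ..pitch import CycleSequence, F0Contour, estimate_f0_contour, extract_cycles
from ..qc import select_stationary_segment
from . import contour, emd, noise, nonlinear, perturbation, spectral

FAMILY_COUNTS = {
    "jitter": 28, "shimmer": 21, "hnr": 4, "gq": 3, "gne": 6, "vfer": 9,
    "emd_er": 6, "mfcc": 39, "f0_related": 3, "wavelet": 182,
    "ppe": 1, "dfa": 1, "rpde": 1,
}

_NAME_FNS = {
    "jitter": perturbation.jitter_names,
    "shimmer": perturbation.shimmer_names,
    "hnr": noise.hnr_names,
    "gq": perturbation.gq_names,
    "gne": noise.gne_names,
    "vfer": noise.vfer_names,
    "emd_er": emd.emd_er_names,
    "mfcc": spectral.mfcc_names,
    "f0_related": contour.f0_related_names,
    "wavelet": contour.wavelet_names,
    "ppe": contour.ppe_names,
    "dfa": nonlinear.dfa_names,
    "rpde": nonlinear.rpde_names,
}


def feature_names() -> list[str]:
    """The frozen, ordered 304-name manifest ("<family>.<measure>")."""
    names: list[str] = []
    for fam, count in FAMILY_COUNTS.items():
        fam_names = _NAME_FNS[fam]()
        assert len(fam_names) == count, (fam, len(fam_names), count)
        names += fam_names
    assert len(names) == 304
    return names


def family_index() -> dict[str, slice]:
    """Map family -> slice of positions in the feature vector."""
    idx = {}
    pos = 0
    for fam, count in FAMILY_COUNTS.items():
        idx[fam] = slice(pos, pos + count)
        pos += count
    return idx


@dataclass
class FeatureVector:
    """Ordered, named 304-value dysphonia profile of one phonation."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def extract_all(p: Phonation, age: float = float("nan"), gender: str = "M",
                norms: contour.NormativeF0Table | None = None,
                f0: F0Contour | None = None) -> FeatureVector:
    """Compute the full battery on the most stationary 2 s segment.

    Any family that cannot be computed flags the recording (raises
    :class:`FeatureFlagged` carrying the family name); values are never
    silently imputed.
    """
    if norms is None:
        norms = contour.NormativeF0Table()
    if f0 is None:
        f0 = estimate_f0_contour(p)
    window = select_stationary_segment(p, f0)
    segment = p.crop(window.start, window.end)
    seg_f0 = estimate_f0_contour(segment)
    cycles: CycleSequence = extract_cycles(segment, seg_f0)

    parts = [
        perturbation.jitter_family(cycles, seg_f0),
        perturbation.shimmer_family(cycles, segment),
        noise.hnr_nhr(segment, seg_f0),
        perturbation.gq_family(cycles),
        noise.gne_family(segment),
        noise.vfer_family(segment),
        emd.emd_er_family(segment),
        spectral.mfcc_family(segment),
        contour.f0_related_family(seg_f0, age, gender, norms),
        contour.wavelet_family(seg_f0),
        contour.ppe(seg_f0),
        nonlinear.dfa(segment),
        nonlinear.rpde(segment),
    ]
    values = np.concatenate(parts)
    if len(values) != 304:
        raise PhonoscreenError(f"battery produced {len(values)} values")
    if not np.all(np.isfinite(values)):
        bad = np.where(~np.isfinite(values))[0][0]
        raise FeatureFlagged(feature_names()[bad].split(".")[0],
                             "non-finite value")
    return FeatureVector(values=values, names=feature_names())
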