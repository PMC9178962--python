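"""Cortical parcellation handling.

The pipeline operates on a fixed, ordered list of region labels.  The default
parcellation has 360 cortical regions (180 per hemisphere), mirroring the
multimodal parcellation commonly used for morphometric similarity mapping.
Labels are opaque strings; no surface geometry is attached.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

N_REGIONS_DEFAULT = 360


def default_labels(n_regions: int = N_REGIONS_DEFAULT) -> list[str]:
    """Generate hemisphere-prefixed region labels ``L_ROI_001 .. R_ROI_180``."""
    half = n_regions // 2
    left = [f"L_ROI_{i + 1:03d}" for i in range(half)]
    right = [f"R_ROI_{i + 1:03d}" for i in range(n_regions - half)]
    return left + right


@dataclass(frozen=True)
class Parcellation:
    """Ordered, unique set of region labels fixed across a whole run."""

    labels: tuple[str, ...] = field(default_factory=lambda: tuple(default_labels()))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parcellation labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("parcellation needs at least 2 regions")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def hash(self) -> str:
        """Short content hash identifying the label list."""
        h = hashlib.sha256("\n".join(self.labels).encode())
        return h.hexdigest()[:12]

    def index_of(self, labels) -> list[int]:
        lut = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in lut]
        if missing:
            raise KeyError(f"unknown region labels: {missing[:5]}"
                           + (" ..." if len(missing) > 5 else ""))
        return [lut[lab] for lab in labels]

    @classmethod
    def of_size(cls, n_regions: int) -> "Parcellation":
        return cls(tuple(default_labels(n_regions)))
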