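"""Region-of-interest maps for both modalities.

The fNIRS probe covers six sensorimotor/parietal regions per hemisphere
(PRCG, POCG, SPL, IPL, SMG, AG); the 24 measurement channels are assigned
to these 12 ROIs by a fixed synthetic channel->region map (two channels per
region), replacing per-participant atlas registration.

The EEG scalp groupings are the eight published electrode lists (E-number
labels of a 128-electrode geodesic net); 24 outer-rim electrodes are
excluded from analysis because they are dominated by eye/face/neck
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FNIRS_REGION_CODES = ("PRCG", "POCG", "SPL", "IPL", "SMG", "AG")

#: channel index -> anatomical region, 24 channels, 2 per (region, hemisphere)
DEFAULT_FNIRS_ROI_MAP: dict[int, str] = {}
for _h, _side in enumerate(("Left", "Right")):
    for _r, _code in enumerate(FNIRS_REGION_CODES):
        for _k in range(2):
            DEFAULT_FNIRS_ROI_MAP[_h * 12 + _r * 2 + _k] = f"{_side} {_code}"

#: scalp grouping -> electrode labels
EEG_ROI_ELECTRODES: dict[str, tuple[str, ...]] = {
    "left frontal": ("E19", "E20", "E23", "E24", "E27", "E28"),
    "right frontal": ("E3", "E4", "E117", "E118", "E123", "E124"),
    "left central": ("E29", "E30", "E35", "E36", "E37", "E41", "E42"),
    "right central": ("E87", "E93", "E103", "E104", "E105", "E110", "E111"),
    "left parietal": ("E47", "E51", "E52", "E53", "E59", "E60"),
    "right parietal": ("E85", "E86", "E91", "E92", "E97", "E98"),
    "left occipital": ("E66", "E69", "E70", "E71", "E74"),
    "right occipital": ("E76", "E82", "E83", "E84", "E89"),
}

#: outer-rim electrodes excluded before any EEG processing
BOUNDARY_ELECTRODES: tuple[str, ...] = (
    "E17", "E38", "E43", "E44", "E48", "E49", "E113", "E114", "E119",
    "E120", "E121", "E125", "E126", "E127", "E128", "E56", "E63", "E68",
    "E73", "E81", "E88", "E94", "E99", "E107",
)

ANALYSIS_ELECTRODES: tuple[str, ...] = tuple(
    e for roi in EEG_ROI_ELECTRODES.values() for e in roi
)


@dataclass(frozen=True)
class RoiMap:
    """Channel/electrode -> named-region assignment for both modalities."""

    fnirs: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_FNIRS_ROI_MAP)
    )
    eeg: dict[str, str] = field(
        default_factory=lambda: {
            e: roi for roi, els in EEG_ROI_ELECTRODES.items() for e in els
        }
    )

    def fnirs_channels(self, roi: str) -> list[int]:
        return [c for c, r in self.fnirs.items() if r == roi]

    def eeg_electrodes(self, roi: str) -> list[str]:
        return [e for e, r in self.eeg.items() if r == roi]

    @property
    def fnirs_rois(self) -> list[str]:
        return sorted(set(self.fnirs.values()))

    @property
    def eeg_rois(self) -> list[str]:
        return sorted(set(self.eeg.values()))


DEFAULT_ROI_MAP = RoiMap()
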