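"""Grouping of channel metrics into lobes and hemispheres.

The double-banana channels are grouped into frontal (F), parieto-occipital
(PO) and temporal (T) lobes of three channels each, per hemisphere; the
T5–O1 / T6–O2 derivations belong to both the PO and T lobes. Midline
channels (Fz–Cz, Cz–Pz) enter no lobe or hemisphere aggregate.

The hemisphere aggregate by default uses the 8 distinct lateral channels.
``strict_nine_term`` reproduces a 9-term variant in clinical use in which the
posterior temporal-occipital channel is counted twice (divisor 9); the two
modes agree whenever all channels carry the same value.

For the average-reference (AVG) montage the same scalp regions are expressed
over the referential electrodes spanned by the bipolar channels of the lobe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DefinitionError

#: Bipolar lobe definitions (left shown; right mirrors).
BIPOLAR_LOBES: dict[str, list[str]] = {
    "F_left": ["Fp1-F3", "F3-C3", "Fp1-F7"],
    "PO_left": ["C3-P3", "P3-O1", "T5-O1"],
    "T_left": ["F7-T3", "T3-T5", "T5-O1"],
    "F_right": ["Fp2-F4", "F4-C4", "Fp2-F8"],
    "PO_right": ["C4-P4", "P4-O2", "T6-O2"],
    "T_right": ["F8-T4", "T4-T6", "T6-O2"],
}

#: Hemisphere channel lists: 8 distinct lateral channels each.
HEMISPHERES: dict[str, list[str]] = {
    "left": ["Fp1-F3", "F3-C3", "Fp1-F7", "C3-P3", "P3-O1", "T5-O1",
             "F7-T3", "T3-T5"],
    "right": ["Fp2-F4", "F4-C4", "Fp2-F8", "C4-P4", "P4-O2", "T6-O2",
              "F8-T4", "T4-T6"],
}

#: 9-term hemisphere multisets with the posterior channel repeated.
HEMISPHERES_STRICT: dict[str, list[str]] = {
    "left": HEMISPHERES["left"] + ["T5-O1"],
    "right": HEMISPHERES["right"] + ["T6-O2"],
}

#: AVG-montage lobes: the referential electrodes of the bipolar channels.
AVG_LOBES: dict[str, list[str]] = {
    "F_left": ["Fp1", "F3", "C3", "F7"],
    "PO_left": ["C3", "P3", "O1", "T5"],
    "T_left": ["F7", "T3", "T5", "O1"],
    "F_right": ["Fp2", "F4", "C4", "F8"],
    "PO_right": ["C4", "P4", "O2", "T6"],
    "T_right": ["F8", "T4", "T6", "O2"],
}

LOBES = ("F_left", "PO_left", "T_left", "F_right", "PO_right", "T_right")


@dataclass
class RegionMap:
    """Named channel groupings for one montage.

    ``regions`` maps region name to an ordered channel list (a list may
    repeat a channel, in which case the repeated channel is weighted
    accordingly).
    """

    montage: str = "bipolar"
    strict_nine_term: bool = False
    regions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.regions:
            return
        if self.montage == "bipolar":
            self.regions = {k: list(v) for k, v in BIPOLAR_LOBES.items()}
            hemis = HEMISPHERES_STRICT if self.strict_nine_term else HEMISPHERES
            for side, chans in hemis.items():
                self.regions[f"H_{side}"] = list(chans)
        elif self.montage == "avg":
            self.regions = {k: list(v) for k, v in AVG_LOBES.items()}
        else:
            raise DefinitionError(f"unknown montage {self.montage!r}")


def lobe_mean(values: dict[str, float], channels: list[str]) -> float:
    """Arithmetic mean of a per-channel metric over a region's channel list.

    Repeated channels (strict hemisphere mode) contribute once per listing.
    """
    missing = [c for c in channels if c not in values]
    if missing:
        raise DefinitionError(
            "region channels missing from values: " + ", ".join(missing))
    return float(np.mean([values[c] for c in channels]))


def region_means(values: dict[str, float], region_map: RegionMap
                 ) -> dict[str, float]:
    """``lobe_mean`` over every region in the map."""
    return {name: lobe_mean(values, chans)
            for name, chans in region_map.regions.items()}
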