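"""Channel montage and the canonical lobe-node ordering.

The whole-head infant montage has 20 channels: per hemisphere 4 temporal,
2 parietal, 2 frontal and 2 occipital. Averaging channels within each
(hemisphere, lobe) pair yields the 8 lobe nodes that both the fNIRS and the
fMRI 8x8 connectivity maps are built on, so every 8x8 map in the package uses
the same node order, :data:`LOBE_NODE_ORDER`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .exceptions import LayoutError

HEMISPHERES = ("L", "R")
LOBES = ("frontal", "parietal", "temporal", "occipital")

#: channels per lobe within one hemisphere
CHANNELS_PER_LOBE = {"frontal": 2, "parietal": 2, "temporal": 4, "occipital": 2}

#: canonical order of the 8 lobe nodes shared by all 8x8 maps
LOBE_NODE_ORDER: Tuple[str, ...] = tuple(
    f"{h}-{lobe}" for h in HEMISPHERES for lobe in LOBES
)


def lobe_node(hemisphere: str, lobe: str) -> str:
    return f"{hemisphere}-{lobe}"


@dataclass(frozen=True)
class MontageLayout:
    """Assignment of each channel to one (hemisphere, lobe) pair.

    Parameters
    ----------
    channel_ids
        Ordered channel identifiers (length 20 for the pipeline montage).
    hemisphere
        Per-channel hemisphere label, ``"L"`` or ``"R"``.
    lobe
        Per-channel lobe label in ``{"frontal", "parietal", "temporal",
        "occipital"}``.
    """

    channel_ids: Tuple[str, ...]
    hemisphere: Tuple[str, ...]
    lobe: Tuple[str, ...]

    def __post_init__(self):
        n = len(self.channel_ids)
        if len(self.hemisphere) != n or len(self.lobe) != n:
            raise LayoutError("channel_ids, hemisphere and lobe must have equal length")
        if len(set(self.channel_ids)) != n:
            raise LayoutError("duplicate channel ids")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise LayoutError(f"unknown hemisphere label {h!r}")
        for l in self.lobe:
            if l not in LOBES:
                raise LayoutError(f"unknown lobe label {l!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def lobe_nodes(self) -> Tuple[str, ...]:
        """The 8 lobe-node labels, in canonical order."""
        return LOBE_NODE_ORDER

    def channel_groups(self) -> Dict[str, List[int]]:
        """Map each canonical lobe node to the indices of its member channels.

        Raises
        ------
        LayoutError
            If any lobe node has no channels (its average is undefined).
        """
        groups: Dict[str, List[int]] = {node: [] for node in LOBE_NODE_ORDER}
        for idx, (h, l) in enumerate(zip(self.hemisphere, self.lobe)):
            groups[lobe_node(h, l)].append(idx)
        empty = [node for node, members in groups.items() if not members]
        if empty:
            raise LayoutError(f"lobe nodes without channels: {', '.join(empty)}")
        return groups

    def node_index(self) -> Dict[str, int]:
        return {node: i for i, node in enumerate(LOBE_NODE_ORDER)}

    def validate_standard(self) -> None:
        """Check the 20-channel whole-head invariants (4T/2P/2F/2O per hemisphere)."""
        if self.n_channels != 20:
            raise LayoutError(f"standard montage has 20 channels, got {self.n_channels}")
        groups = self.channel_groups()
        for h in HEMISPHERES:
            for lobe, expected in CHANNELS_PER_LOBE.items():
                got = len(groups[lobe_node(h, lobe)])
                if got != expected:
                    raise LayoutError(
                        f"{h}-{lobe}: expected {expected} channels, got {got}"
                    )


def default_montage() -> MontageLayout:
    """The standard 20-channel whole-head montage.

    Channels are ordered hemisphere-major (all left, then all right) and
    lobe-major within hemisphere, following :data:`LOBE_NODE_ORDER`.
    """
    ids: List[str] = []
    hemis: List[str] = []
    lobes: List[str] = []
    k = 1
    for h in HEMISPHERES:
        for lobe in LOBES:
            for _ in range(CHANNELS_PER_LOBE[lobe]):
                ids.append(f"ch{k:02d}")
                hemis.append(h)
                lobes.append(lobe)
                k += 1
    layout = MontageLayout(tuple(ids), tuple(hemis), tuple(lobes))
    layout.validate_standard()
    return layout
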