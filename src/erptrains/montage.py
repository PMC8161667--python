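"""Electrode montages and region/site assignment.

The analysis collapses channels into a 2 x 3 grid of scalp cells:
region (frontal, posterior) x site (left, central, right).  The default
test montage carries two channels per cell (12 channels); a denser
128-channel geodesic-style layout is available for realism.  Channel
positions are schematic 2D head coordinates (x: left->right, y:
posterior->anterior, unit head radius) and are used only for
neighbour-based interpolation of bad channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("frontal", "posterior")
SITES = ("left", "central", "right")


@dataclass(frozen=True)
class Montage:
    """Channel labels, 2D positions and region/site map."""

    ch_names: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    region_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, (region, site) in self.region_map.items():
            if ch not in self.ch_names:
                raise ValueError(f"region_map references unknown channel {ch!r}")
            if region not in REGIONS or site not in SITES:
                raise ValueError(f"invalid region/site for {ch!r}: {(region, site)}")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def cell_channels(self, region: str, site: str | None = None) -> list[str]:
        """Channels assigned to one region x site cell (or the whole region)."""
        return [
            ch
            for ch, (r, s) in self.region_map.items()
            if r == region and (site is None or s == site)
        ]

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[ch] for ch in self.ch_names], dtype=float)

    def validate_cells(self) -> None:
        """Require every region x site cell to be non-empty."""
        for region in REGIONS:
            for site in SITES:
                if not self.cell_channels(region, site):
                    raise ValueError(f"empty montage cell: {region}/{site}")


def default_montage() -> Montage:
    """16-channel test montage: two channels per region x site cell.

    Four central channels (C3, Cz, C4, Oz) carry no region assignment,
    mirroring real analyses that use only a subset of a dense net; they
    keep the average reference from making the posterior regional mean
    an exact mirror of the frontal one.
    """
    spec = {
        # label: (x, y, region, site)
        "F7": (-0.7, 0.55, "frontal", "left"),
        "F3": (-0.4, 0.6, "frontal", "left"),
        "Fz": (0.0, 0.65, "frontal", "central"),
        "FCz": (0.0, 0.4, "frontal", "central"),
        "F4": (0.4, 0.6, "frontal", "right"),
        "F8": (0.7, 0.55, "frontal", "right"),
        "P7": (-0.7, -0.55, "posterior", "left"),
        "P3": (-0.4, -0.6, "posterior", "left"),
        "Pz": (0.0, -0.65, "posterior", "central"),
        "POz": (0.0, -0.8, "posterior", "central"),
        "P4": (0.4, -0.6, "posterior", "right"),
        "P8": (0.7, -0.55, "posterior", "right"),
        "C3": (-0.4, 0.0, None, None),
        "Cz": (0.0, 0.0, None, None),
        "C4": (0.4, 0.0, None, None),
        "Oz": (0.0, -0.95, None, None),
    }
    names = tuple(spec)
    positions = {ch: (x, y) for ch, (x, y, _, _) in spec.items()}
    region_map = {ch: (r, s) for ch, (_, _, r, s) in spec.items() if r is not None}
    return Montage(names, positions, region_map)


def dense_montage(n_rings: int = 6) -> Montage:
    """Schematic high-density layout (concentric rings; 127 channels for 6 rings).

    Channels in the front/back thirds of the head are assigned to frontal
    and posterior regions respectively, split by azimuth into left, central
    and right sites; the central band stays unassigned, mimicking analyses
    that use only a subset of a dense net.
    """
    names: list[str] = []
    positions: dict[str, tuple[float, float]] = {}
    region_map: dict[str, tuple[str, str]] = {}
    idx = 1
    names.append(f"E{idx}")
    positions[f"E{idx}"] = (0.0, 0.0)
    idx += 1
    for ring in range(1, n_rings + 1):
        radius = ring / n_rings
        n_in_ring = 6 * ring
        for k in range(n_in_ring):
            theta = 2 * np.pi * k / n_in_ring
            x, y = radius * np.sin(theta), radius * np.cos(theta)
            label = f"E{idx}"
            names.append(label)
            positions[label] = (float(x), float(y))
            if y > 0.3:
                region = "frontal"
            elif y < -0.3:
                region = "posterior"
            else:
                idx += 1
                continue
            if x < -0.2:
                site = "left"
            elif x > 0.2:
                site = "right"
            else:
                site = "central"
            region_map[label] = (region, site)
            idx += 1
    return Montage(tuple(names), positions, region_map)
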