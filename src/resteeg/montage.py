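"""Electrode montages and anatomical channel clusters.

The cluster scheme groups a 10-10 montage into twelve regions of interest
used for regional band-power and complexity averaging: midfrontal (MF),
frontal left/right (FL/FR), central (C), central-temporal left/right
(CTL/CTR), posterior-central (PC), parietal-temporal left/right (PTL/PTR)
and occipital central/left/right (OC/OL/OR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Canonical ordered 10-10 label list used by the synthetic generator.
STANDARD_1010: tuple[str, ...] = (
    "Fz", "Cz", "Pz", "Oz",
    "Fp1", "Fp2", "F3", "F4", "F7", "F8",
    "C3", "C4", "T7", "T8",
    "P3", "P4", "P7", "P8", "O1", "O2",
    "Fpz", "AFz", "AF3", "AF4", "FC1", "FC2", "FC5", "FC6", "FCz",
    "C1", "C2", "C5", "C6",
    "CP1", "CP2", "CP5", "CP6", "CPz",
    "P1", "P2", "P5", "P6", "TP7", "TP8",
    "PO3", "PO4", "PO7", "PO8", "POz",
    "F5", "F6", "FT7", "FT8",
)

#: 19-channel 10-20 subset conventionally used for coherence analysis.
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

CLUSTER_NAMES: frozenset[str] = frozenset(
    {"MF", "FL", "FR", "C", "CTL", "CTR", "PC", "PTL", "PTR", "OC", "OL", "OR",
     "C-mid", "CP-mid"}
)

#: Default regional grouping over the 10-10 montage.
DEFAULT_CLUSTERS: dict[str, list[str]] = {
    "MF": ["Fpz", "Fp1", "Fp2", "AFz", "AF3", "AF4", "Fz"],
    "FL": ["F3", "F5", "F7", "FC5", "FT7"],
    "FR": ["F4", "F6", "F8", "FC6", "FT8"],
    "C": ["FCz", "FC1", "FC2", "Cz", "C1", "C2"],
    "CTL": ["C3", "C5", "T7", "CP5"],
    "CTR": ["C4", "C6", "T8", "CP6"],
    "PC": ["CPz", "CP1", "CP2", "Pz", "P1", "P2"],
    "PTL": ["P3", "P5", "P7", "TP7"],
    "PTR": ["P4", "P6", "P8", "TP8"],
    "OC": ["POz", "Oz"],
    "OL": ["PO3", "PO7", "O1"],
    "OR": ["PO4", "PO8", "O2"],
}


@dataclass
class ClusterMap:
    """Named electrode groupings over a montage.

    Parameters
    ----------
    clusters
        Mapping from cluster name to a list of channel labels.
    montage_name
        Free-form montage identifier (e.g. ``"standard_1010"``).
    """

    clusters: dict[str, list[str]]
    montage_name: str = "standard_1010"

    def __post_init__(self) -> None:
        for name, chans in self.clusters.items():
            if name not in CLUSTER_NAMES:
                raise ValueError(f"unknown cluster name {name!r}")
            if not chans:
                raise ValueError(f"cluster {name!r} is empty")

    @property
    def channels(self) -> list[str]:
        """All channels referenced by any cluster, in first-seen order."""
        seen: dict[str, None] = {}
        for chans in self.clusters.values():
            for ch in chans:
                seen.setdefault(ch)
        return list(seen)

    def validate_against(self, channels: list[str]) -> None:
        """Raise ``KeyError`` naming the first cluster channel absent from
        *channels*."""
        have = set(channels)
        for name, chans in self.clusters.items():
            for ch in chans:
                if ch not in have:
                    raise KeyError(
                        f"cluster {name!r} references channel {ch!r} "
                        "not present in the recording"
                    )

    def restrict(self, channels: list[str]) -> "ClusterMap":
        """Drop channels not in *channels*; clusters left empty are removed."""
        have = set(channels)
        kept = {
            name: [ch for ch in chans if ch in have]
            for name, chans in self.clusters.items()
        }
        kept = {name: chans for name, chans in kept.items() if chans}
        if not kept:
            raise ValueError("no cluster channel present in the recording")
        return ClusterMap(kept, self.montage_name)

    @classmethod
    def default(cls) -> "ClusterMap":
        return cls({k: list(v) for k, v in DEFAULT_CLUSTERS.items()})

    @classmethod
    def from_yaml(cls, path) -> "ClusterMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        montage = raw.pop("montage_name", "standard_1010") if isinstance(raw, dict) else "standard_1010"
        clusters = raw.get("clusters", raw) if isinstance(raw, dict) else raw
        return cls({str(k): [str(c) for c in v] for k, v in clusters.items()}, montage)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"montage_name": self.montage_name, "clusters": self.clusters},
                fh, sort_keys=False,
            )


def montage_channels(n_channels: int, montage: str = "standard_1010") -> list[str]:
    """First *n_channels* labels of a named montage."""
    if montage == "standard_1010":
        pool = STANDARD_1010
    elif montage == "standard_1020":
        pool = STANDARD_1020
    else:
        raise ValueError(f"unknown montage {montage!r}")
    if n_channels > len(pool):
        raise ValueError(
            f"montage {montage!r} has only {len(pool)} labels, "
            f"{n_channels} requested"
        )
    return list(pool[:n_channels])
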