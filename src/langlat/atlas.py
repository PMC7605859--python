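"""SENT_CORE atlas handling.

The sentence-processing supramodal network (SENT_CORE) is a set of 18
homotopic pairs of frontal and temporal regions of interest (hROIs), each
pair having one left- and one right-hemisphere member.  Three pairs — the
inferior frontal gyrus pars triangularis (F3t) and two superior temporal
sulcus regions (STS3, STS4) — act as intrinsic-connectivity hubs and form
the SENT_HUBS subset.

Per-hemisphere hROI volumes are used downstream as weights for the
volumetric-mean network asymmetries, so they are carried by the atlas and
never hard-coded.  A bundled fixture atlas ships with the package
(:func:`default_atlas`); real volumes can be supplied from file with
:func:`load_atlas`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "HUB_PAIRS",
    "HRoi",
    "Atlas",
    "ValidationError",
    "load_atlas",
    "write_atlas",
    "default_atlas",
]

#: Canonical hub pair names (intrinsic-connectivity hubs of SENT_CORE).
HUB_PAIRS = ("F3t", "STS3", "STS4")

HEMISPHERES = ("L", "R")


class ValidationError(ValueError):
    """Raised when an atlas (or atlas file) violates a structural invariant."""


@dataclass(frozen=True)
class HRoi:
    """One hemispheric region of interest (one member of a homotopic pair)."""

    pair_name: str
    hemisphere: str  # "L" or "R"
    volume_mm3: float
    is_hub: bool

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"hROI {self.pair_name}: hemisphere must be L or R, got {self.hemisphere!r}"
            )
        if not self.volume_mm3 > 0:
            raise ValidationError(
                f"hROI {self.pair_name}/{self.hemisphere}: volume must be positive, "
                f"got {self.volume_mm3}"
            )


@dataclass
class Atlas:
    """A set of homotopic hROI pairs.

    ``entries`` holds both hemispheres of every pair.  Pair order is the
    order of first appearance and fixes the column order of all derived
    matrices (left block then right block).
    """

    entries: list[HRoi]
    name: str = "SENT_CORE"
    _by_key: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._by_key = {}
        order: list[str] = []
        for roi in self.entries:
            key = (roi.pair_name, roi.hemisphere)
            if key in self._by_key:
                raise ValidationError(
                    f"duplicate hROI row ({roi.pair_name}, {roi.hemisphere})"
                )
            self._by_key[key] = roi
            if roi.pair_name not in order:
                order.append(roi.pair_name)
        self._pair_order = tuple(order)
        for pair in self._pair_order:
            left = self._by_key.get((pair, "L"))
            right = self._by_key.get((pair, "R"))
            if left is None or right is None:
                missing = "L" if left is None else "R"
                raise ValidationError(
                    f"pair {pair!r} is missing its {missing}-hemisphere partner"
                )
            if left.is_hub != right.is_hub:
                raise ValidationError(
                    f"pair {pair!r}: is_hub differs between hemispheres"
                )

    # -- structure ---------------------------------------------------------

    @property
    def pair_names(self) -> tuple[str, ...]:
        return self._pair_order

    @property
    def n_pairs(self) -> int:
        return len(self._pair_order)

    @property
    def hub_names(self) -> tuple[str, ...]:
        return tuple(p for p in self._pair_order if self._by_key[(p, "L")].is_hub)

    def roi(self, pair_name: str, hemisphere: str) -> HRoi:
        try:
            return self._by_key[(pair_name, hemisphere)]
        except KeyError:
            raise KeyError(f"no hROI ({pair_name}, {hemisphere}) in atlas {self.name}")

    def partner(self, roi: HRoi) -> HRoi:
        """The homotopic partner of ``roi`` (an involution)."""
        other = "R" if roi.hemisphere == "L" else "L"
        return self.roi(roi.pair_name, other)

    def pair_volume(self, pair_name: str) -> float:
        """Pair weight: sum of the left and right member volumes (mm^3)."""
        return self.roi(pair_name, "L").volume_mm3 + self.roi(pair_name, "R").volume_mm3

    def pairs(self, roi_set: str = "CORE") -> tuple[str, ...]:
        """Pair names of a region set: ``"CORE"`` (all) or ``"HUBS"``."""
        if roi_set == "CORE":
            return self._pair_order
        if roi_set == "HUBS":
            return self.hub_names
        raise ValueError(f"unknown roi_set {roi_set!r} (expected 'CORE' or 'HUBS')")

    def column_labels(self) -> list[str]:
        """Time-series / matrix column labels: all left then all right hROIs."""
        return [f"{p}_L" for p in self._pair_order] + [
            f"{p}_R" for p in self._pair_order
        ]

    def subset(self, pair_names: list[str], name: str | None = None) -> "Atlas":
        keep = set(pair_names)
        entries = [r for r in self.entries if r.pair_name in keep]
        return Atlas(entries, name=name or f"{self.name}_subset")

    # -- validation --------------------------------------------------------

    def validate(
        self,
        n_pairs: int | None = 18,
        n_hubs: int | None = 3,
        hub_names: tuple[str, ...] | None = HUB_PAIRS,
    ) -> "Atlas":
        """Check the canonical SENT_CORE invariants; return self if valid."""
        if n_pairs is not None and self.n_pairs != n_pairs:
            raise ValidationError(
                f"expected {n_pairs} pairs, found {self.n_pairs} in atlas {self.name}"
            )
        hubs = self.hub_names
        if n_hubs is not None and len(hubs) != n_hubs:
            raise ValidationError(
                f"expected {n_hubs} hub pairs, found {len(hubs)}: {sorted(hubs)}"
            )
        if hub_names is not None and set(hubs) != set(hub_names):
            raise ValidationError(
                f"hub pairs must be {sorted(hub_names)}, found {sorted(hubs)}"
            )
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_name": [r.pair_name for r in self.entries],
                "hemisphere": [r.hemisphere for r in self.entries],
                "volume_mm3": [r.volume_mm3 for r in self.entries],
                "is_hub": [int(r.is_hub) for r in self.entries],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atlas):
            return NotImplemented
        return self.name == other.name and self.entries == other.entries


REQUIRED_COLUMNS = ("pair_name", "hemisphere", "volume_mm3", "is_hub")


def _frame_to_atlas(table: pd.DataFrame, name: str) -> Atlas:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"atlas file is missing columns {missing}")
    entries = []
    for idx, row in table.iterrows():
        volume = float(row["volume_mm3"])
        if not volume > 0:
            raise ValidationError(
                f"row {idx} ({row['pair_name']}, {row['hemisphere']}): "
                f"non-positive volume {volume}"
            )
        entries.append(
            HRoi(
                pair_name=str(row["pair_name"]),
                hemisphere=str(row["hemisphere"]),
                volume_mm3=volume,
                is_hub=bool(int(row["is_hub"])),
            )
        )
    return Atlas(entries, name=name)


def load_atlas(
    path,
    *,
    name: str = "SENT_CORE",
    n_pairs: int | None = 18,
    n_hubs: int | None = 3,
    hub_names: tuple[str, ...] | None = HUB_PAIRS,
) -> Atlas:
    """Read an atlas from delimited text (comma or tab, sniffed from header).

    The file needs one row per hROI with columns
    ``pair_name, hemisphere, volume_mm3, is_hub`` (hemisphere L/R, is_hub 0/1).
    Pass ``n_pairs=None`` (etc.) to skip the canonical SENT_CORE size checks,
    e.g. for reduced test atlases.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    table = pd.read_csv(path, sep=sep)
    atlas = _frame_to_atlas(table, name=name)
    return atlas.validate(n_pairs=n_pairs, n_hubs=n_hubs, hub_names=hub_names)


def write_atlas(atlas: Atlas, path, sep: str = "\t") -> None:
    atlas.to_frame().to_csv(path, sep=sep, index=False)


def default_atlas() -> Atlas:
    """The bundled 18-pair SENT_CORE fixture atlas.

    Pair names follow the SENSAAS naming style and include the three hubs
    (F3t, STS3, STS4); volumes are plausible synthetic values (the source
    publication does not print hROI volumes), fixed once at packaging time.
    """
    resource = importlib.resources.files("langlat").joinpath(
        "data/sent_core_atlas.tsv"
    )
    with importlib.resources.as_file(resource) as path:
        return load_atlas(path)
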