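"""Parcel registries.

An :class:`Atlas` is the ordered universe of brain parcels over which
features are constructed and multiple-comparison correction is defined.
The default registry mirrors a 400-parcel cortical parcellation augmented
with 36 subcortical parcels (436 parcels total).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

__all__ = ["Atlas", "default_atlas", "make_atlas"]


@dataclass(frozen=True)
class Atlas:
    """Ordered parcel registry.

    Parameters
    ----------
    parcel_ids
        Strictly increasing integer parcel ids.
    names
        One label per parcel.
    is_subcortical
        Boolean flag per parcel (False = cortical).
    """

    parcel_ids: tuple
    names: tuple
    is_subcortical: tuple

    def __post_init__(self):
        ids = tuple(int(i) for i in self.parcel_ids)
        object.__setattr__(self, "parcel_ids", ids)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "is_subcortical", tuple(bool(b) for b in self.is_subcortical))
        if len(ids) != len(set(ids)):
            raise ValueError("parcel ids must be unique")
        if any(b > a for a, b in zip(ids[1:], ids)):
            raise ValueError("parcel ids must be ordered (strictly increasing)")
        if not (len(ids) == len(self.names) == len(self.is_subcortical)):
            raise ValueError("parcel_ids, names and is_subcortical must have equal length")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def index_of(self, parcel_id: int) -> int:
        """Position of ``parcel_id`` in atlas order."""
        try:
            return self.parcel_ids.index(int(parcel_id))
        except ValueError:
            raise KeyError(f"parcel id {parcel_id} not in atlas") from None

    def hash(self) -> str:
        """Stable content hash used to detect atlas mismatches between artifacts."""
        h = hashlib.sha256()
        for pid, name, sub in zip(self.parcel_ids, self.names, self.is_subcortical):
            h.update(f"{pid}\t{name}\t{int(sub)}\n".encode())
        return h.hexdigest()[:16]


def make_atlas(n_parcels: int, n_subcortical: int = 0) -> Atlas:
    """Build a generic atlas with ids 1..n; the last ``n_subcortical`` are subcortical."""
    if n_parcels < 1 or n_subcortical < 0 or n_subcortical > n_parcels:
        raise ValueError("invalid parcel counts")
    n_cort = n_parcels - n_subcortical
    ids = tuple(range(1, n_parcels + 1))
    names = tuple(
        f"Cortex_{i:03d}" if i <= n_cort else f"Subcortex_{i - n_cort:02d}"
        for i in ids
    )
    sub = tuple(i > n_cort for i in ids)
    return Atlas(ids, names, sub)


def default_atlas() -> Atlas:
    """The default 436-parcel registry: 400 cortical + 36 subcortical parcels."""
    return make_atlas(436, n_subcortical=36)
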