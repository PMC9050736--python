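"""3-D expression-domain volumetry for multi-channel HCR stacks.

Each channel of a stack is binarized with a single global Otsu threshold; a
"total" reference mask comes from Otsu on the voxelwise sum of all channels
(the markers jointly tile the whole organoid, so the sum covers it).  Voxel
counts are converted to µm³ with the anisotropic voxel size (light-sheet
stacks here are Z = 2 µm, XY = 0.391 µm).  Lineage domains are Boolean
combinations of the SOX2, BRACHYURY and UNCX4.1 masks:

* Neural  = SOX2+ & BRACHYURY-
* Somite  = UNCX4.1+        (no exclusion applied)
* PSM     = BRACHYURY+ & SOX2-
* NMP     = BRACHYURY+ & SOX2+

all restricted to the total somitoid mask.  By construction Neural + NMP
equals the SOX2-positive volume and PSM + NMP the BRACHYURY-positive volume,
exactly, at the voxel level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import filters

from .grids import ImageGrid, LabeledMask

__all__ = [
    "channel_masks_3d",
    "total_reference_mask",
    "mask_volume",
    "lineage_domain_volumes",
    "LineageVolumeReport",
]

#: canonical channel roles; mapping is configurable and case-insensitive
DEFAULT_CHANNELS = {"sox2": "SOX2", "brachyury": "BRACHYURY",
                    "uncx4.1": "UNCX4.1"}


@dataclass
class LineageVolumeReport:
    """Volumes (µm³) of the lineage marker expression domains."""

    channel_volumes: dict          # raw per-channel positive volumes
    total_volume: float            # whole-somitoid reference volume
    domain_volumes: dict           # Neural / Somite / PSM / NMP
    domain_fractions: dict         # of total (Somite overlaps others; may sum > 1)
    voxel_size: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "channel_volumes_um3": self.channel_volumes,
            "total_volume_um3": self.total_volume,
            "domain_volumes_um3": self.domain_volumes,
            "domain_fractions": self.domain_fractions,
            "voxel_size_um": list(self.voxel_size),
        }


def _otsu_mask(data: np.ndarray, pixel_size, prov: dict) -> LabeledMask:
    if np.ptp(data) == 0:
        warnings.warn("constant channel: binarization is degenerate",
                      stacklevel=3)
        prov = dict(prov, degenerate=True, threshold=float(data.flat[0]))
        return LabeledMask(np.zeros(data.shape, dtype=bool), pixel_size, prov)
    thr = float(filters.threshold_otsu(data))
    return LabeledMask(data > thr, pixel_size, dict(prov, threshold=thr))


def channel_masks_3d(stack: ImageGrid,
                     overrides: dict[str, LabeledMask] | None = None
                     ) -> dict[str, LabeledMask]:
    """One global-Otsu mask per channel of a multi-channel 3-D stack.

    ``overrides`` maps channel names to externally corrected masks (e.g.
    manual fixes of low-signal channels); an override is used verbatim and
    recorded in the mask's provenance.
    """
    if stack.channel_names is None:
        raise ValueError("stack must have named channels")
    overrides = {k.lower(): v for k, v in (overrides or {}).items()}
    out: dict[str, LabeledMask] = {}
    for name in stack.channel_names:
        if name.lower() in overrides:
            ov = overrides[name.lower()]
            if ov.mask.shape != stack.data.shape[1:]:
                raise ValueError(f"override for {name} has shape "
                                 f"{ov.mask.shape}, stack is "
                                 f"{stack.data.shape[1:]}")
            out[name] = LabeledMask(ov.mask, stack.pixel_size,
                                    {"method": "override",
                                     **ov.provenance})
        else:
            out[name] = _otsu_mask(stack.channel(name), stack.pixel_size,
                                   {"method": "otsu", "channel": name})
    return out


def total_reference_mask(stack: ImageGrid) -> LabeledMask:
    """Otsu mask of the artificial sum-of-all-channels image.

    Requires at least two channels — for a single channel the sum adds
    nothing and the per-channel mask should be used directly.
    """
    if stack.channel_names is None or stack.data.shape[0] < 2:
        raise ValueError("total_reference_mask needs >= 2 channels; for a "
                         "single channel use channel_masks_3d")
    total = stack.data.astype(np.float64).sum(axis=0)  # widened: no saturation
    return _otsu_mask(total, stack.pixel_size,
                      {"method": "otsu", "channel": "sum"})


def mask_volume(mask: LabeledMask) -> float:
    """Volume in µm³: positive-voxel count times the voxel volume."""
    if mask.mask.ndim != 3:
        raise ValueError("mask_volume expects a 3-D mask")
    if len(mask.pixel_size) != 3:
        raise ValueError("3-D voxel sizes (dz, dy, dx) are required")
    dz, dy, dx = mask.pixel_size
    return float(int(mask.mask.sum()) * dz * dy * dx)


def lineage_domain_volumes(masks: dict[str, LabeledMask],
                           total: LabeledMask,
                           channel_map: dict[str, str] | None = None
                           ) -> LineageVolumeReport:
    """Boolean lineage-domain volumes from per-channel masks.

    ``channel_map`` maps the roles ``sox2``, ``brachyury``, ``uncx4.1`` to
    channel names present in ``masks`` (case-insensitive; defaults to the
    marker names themselves).
    """
    cmap = {k.lower(): v for k, v in (channel_map or DEFAULT_CHANNELS).items()}
    lowered = {k.lower(): v for k, v in masks.items()}

    def get(role: str) -> LabeledMask:
        name = cmap.get(role, role)
        try:
            return lowered[name.lower()]
        except KeyError:
            raise ValueError(f"required channel {name!r} (role {role}) "
                             f"missing from {sorted(masks)}") from None

    sox2, bra, uncx = get("sox2"), get("brachyury"), get("uncx4.1")
    for name, m in [("total", total), ("sox2", sox2), ("brachyury", bra),
                    ("uncx4.1", uncx)]:
        if m.mask.shape != total.mask.shape:
            raise ValueError(f"mask geometry mismatch for {name}: "
                             f"{m.mask.shape} vs {total.mask.shape}")
        if tuple(m.pixel_size) != tuple(total.pixel_size):
            raise ValueError(f"voxel size mismatch for {name}")

    t = total.mask
    s, b, u = sox2.mask & t, bra.mask & t, uncx.mask & t
    domains = {
        "Neural": s & ~b,
        "Somite": u,            # deliberately not exclusive of other markers
        "PSM": b & ~s,
        "NMP": b & s,
    }
    vox = tuple(total.pixel_size)
    vol = float(np.prod(vox))
    total_volume = int(t.sum()) * vol
    domain_volumes = {k: int(v.sum()) * vol for k, v in domains.items()}
    channel_volumes = {k: int((m.mask & t).sum()) * vol
                       for k, m in masks.items()}
    fractions = {k: (v / total_volume if total_volume > 0 else 0.0)
                 for k, v in domain_volumes.items()}
    return LineageVolumeReport(
        channel_volumes=channel_volumes, total_volume=total_volume,
        domain_volumes=domain_volumes, domain_fractions=fractions,
        voxel_size=vox,
        provenance={"restricted_to_total": True})
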