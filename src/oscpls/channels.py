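"""Virtual-channel metadata: 90 cortical/subcortical AAL regions.

The virtual channels correspond to the 90 non-cerebellar regions of the AAL
parcellation (45 bilateral pairs). Region labels are the standard AAL names
with ``_L``/``_R`` hemisphere suffixes.

Coordinates returned by :func:`channel_table` are SYNTHETIC placeholders laid
out deterministically on a sphere — they stand in for atlas centroids purely
so that the metadata table has the documented (label, x, y, z) shape. They
are metadata only and are never used in any computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["AAL90_LABELS", "channel_table"]

_AAL_REGIONS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: The 90 region labels, left/right interleaved, cerebellum excluded.
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{region}_{hemi}" for region in _AAL_REGIONS for hemi in ("L", "R")
)


def channel_table(n_channels: int = 90) -> pd.DataFrame:
    """Channel metadata table: region label plus synthetic MNI-like x/y/z.

    For ``n_channels`` <= 90 the first ``n_channels`` AAL labels are used;
    beyond 90, generic ``ch###`` labels are appended. Coordinates are a
    deterministic Fibonacci-sphere layout (radius 70 mm), mirrored in x for
    the right hemisphere — synthetic placeholders, not atlas centroids.
    """
    labels = list(AAL90_LABELS[:n_channels])
    labels += [f"ch{i:03d}" for i in range(len(labels), n_channels)]

    # Fibonacci sphere per bilateral pair, x mirrored across hemispheres.
    n_pairs = (n_channels + 1) // 2
    k = np.arange(n_pairs)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (k + 0.5) / max(n_pairs, 1)
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    phi = 2 * np.pi * k / golden
    base = np.column_stack([np.abs(r * np.cos(phi)), r * np.sin(phi), z]) * 70.0
    coords = np.repeat(base, 2, axis=0)[:n_channels]
    coords[::2, 0] *= -1  # left hemisphere gets negative x

    return pd.DataFrame(
        {
            "channel": labels,
            "mni_x": np.round(coords[:, 0], 1),
            "mni_y": np.round(coords[:, 1], 1),
            "mni_z": np.round(coords[:, 2], 1),
        }
    )
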