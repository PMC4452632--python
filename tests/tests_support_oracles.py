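"""Shared brute-force oracles and stack builders for the test suite."""

import numpy as np
import pandas as pd

from sirtsim.microscopy import SectionStack


def make_stack(xyz, section_thickness_um=20.0, n_sections=10, biopsy_id=0):
    """Build a SectionStack directly from sphere coordinates (z measured
    from the stack top)."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    dz = section_thickness_um / 1000.0
    idx = np.floor(xyz[:, 2] / dz).astype(int)
    records = pd.DataFrame(
        {
            "sphere_id": np.arange(len(xyz)),
            "x_mm": xyz[:, 0],
            "y_mm": xyz[:, 1],
            "z_mm": xyz[:, 2],
            "section_index": idx,
        }
    )
    return SectionStack(
        biopsy_id=biopsy_id,
        n_sections=n_sections,
        section_thickness_um=section_thickness_um,
        records=records,
        sectioned_fraction=1.0,
        sectioned_volume_mm3=1.0,
    )


def brute_force_locations(points, radius):
    """Union-find over the all-pairs distance matrix (independent oracle
    for single-linkage grouping)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())
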