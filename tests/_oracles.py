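"""Independent brute-force oracles used by the tests.

These deliberately re-derive results from first principles (8-corner
trilinear weights, voxel-in-cylinder enumeration, exhaustive rank-assignment
enumeration) without calling the code paths they check.
"""

import itertools

import numpy as np


def trilinear_oracle(values, idx):
    """Trilinear interpolation at a single fractional index, straight from
    the 8-corner formula."""
    i, j, k = int(np.floor(idx[0])), int(np.floor(idx[1])), int(np.floor(idx[2]))
    i = min(i, values.shape[0] - 2)
    j = min(j, values.shape[1] - 2)
    k = min(k, values.shape[2] - 2)
    fx, fy, fz = idx[0] - i, idx[1] - j, idx[2] - k
    total = 0.0
    for di, dj, dk in itertools.product((0, 1), repeat=3):
        w = ((fx if di else 1 - fx)
             * (fy if dj else 1 - fy)
             * (fz if dk else 1 - fz))
        total += w * values[i + di, j + dj, k + dk]
    return total


def voxel_cylinder_verdict(vol, lm, probe_radius_mm, threshold_hu=400.0,
                           step_mm=1.0):
    """Brute-force accessibility verdict: test every voxel whose centre lies
    inside the probe cylinder against the threshold, bin voxels into 1 mm
    stations, and apply the same entry/exit run exemption.

    Returns (accessible, cortical_station_mask).
    """
    entry = lm.entry.as_array()
    direction = lm.direction
    length = lm.separation_mm

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
    centers = vol.index_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    rel = centers - entry
    axial = rel @ direction
    radial = np.linalg.norm(rel - np.outer(axial, direction), axis=1)
    inside = (axial >= 0) & (axial <= length) & (radial <= probe_radius_mm)

    n_stations = int(np.floor(length / step_mm)) + 1
    arcs = np.arange(n_stations) * step_mm
    if length - arcs[-1] > 1e-9:
        arcs = np.append(arcs, length)
        n_stations += 1
    hot = vol.values.reshape(-1)[inside] > threshold_hu

    # a voxel has finite extent: mark every station its axial footprint
    # overlaps (half a step plus half a voxel diagonal)
    half_window = 0.5 * step_mm + 0.5 * float(np.linalg.norm(vol.spacing))
    cortical = np.zeros(n_stations, dtype=bool)
    for a in axial[inside][hot]:
        cortical |= np.abs(arcs - a) <= half_window

    # run rule: maximal contiguous cortical runs; entry run contains station
    # 0, exit run contains the last station, anything else is interior
    accessible = True
    i = 0
    while i < n_stations:
        if cortical[i]:
            j = i
            while j + 1 < n_stations and cortical[j + 1]:
                j += 1
            is_entry, is_exit = i == 0, j == n_stations - 1
            if (not is_entry and not is_exit) or (is_entry and is_exit):
                accessible = False
            i = j + 1
        else:
            i += 1
    return accessible, cortical


def mann_whitney_exact_oracle(a, b):
    """Exhaustive two-sided Mann-Whitney p-value via the pair-count
    definition of U (counts of a>b plus half-ties), enumerating every
    assignment of the pooled observations to group a."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a, n_b = len(a), len(b)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    mu = n_a * n_b / 2.0
    obs = abs(u_stat(a, b) - mu)
    count = total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n_a + n_b) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def chi_square_oracle(table):
    """Spreadsheet-style Pearson statistic: explicit margins and cell loop."""
    table = [list(map(float, row)) for row in table]
    n = sum(sum(row) for row in table)
    row_tot = [sum(row) for row in table]
    col_tot = [sum(row[j] for row in table) for j in range(len(table[0]))]
    stat = 0.0
    for i, row in enumerate(table):
        for j, o in enumerate(row):
            e = row_tot[i] * col_tot[j] / n
            stat += (o - e) ** 2 / e
    return stat
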