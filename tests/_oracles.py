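"""Independent reference implementations used to check the package.

Deliberately naive: plain Python loops and closed-form geometry, sharing
no code with the implementation under test.
"""

import math

import numpy as np


def brute_force_hbonds(frame, selection_a, selection_b, max_da, max_hda,
                       h_cutoff=1.25):
    """All-pairs O(n^2) hydrogen-bond scan.

    Returns the set of (donor, hydrogen, acceptor) index triples crossing
    the two selections under the distance/angle criteria.
    """
    coords = frame.coords
    elements = [a.element.upper() for a in frame.atoms]
    hydrogens = [i for i in range(len(elements)) if elements[i] == "H"]

    def polar(sel):
        return [i for i in sel if elements[i] in ("N", "O")]

    def donors(sel):
        pairs = []
        for d in polar(sel):
            for h in hydrogens:
                if np.linalg.norm(coords[h] - coords[d]) <= h_cutoff:
                    pairs.append((d, h))
        return pairs

    found = set()
    for sel_d, sel_a in ((selection_a, selection_b), (selection_b, selection_a)):
        for d, h in donors(sel_d):
            for a in polar(sel_a):
                if a == d or a == h:
                    continue
                da = coords[a] - coords[d]
                dist = float(np.linalg.norm(da))
                if dist > max_da:
                    continue
                dh = coords[h] - coords[d]
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle <= max_hda:
                    found.add((d, h, a))
    return found


def two_pointer_conversions(endpoint_labels):
    """Conversion count by scanning only the closed/open endpoint frames.

    ``endpoint_labels`` is any sequence of 'closed'/'semi_open'/'open'.
    """
    endpoints = [s for s in endpoint_labels if s in ("closed", "open")]
    return sum(1 for a, b in zip(endpoints, endpoints[1:]) if a != b)


def rotate_about(point, axis, angle_deg, coords):
    """Rodrigues rotation of coords about an axis through a point."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    theta = math.radians(angle_deg)
    shifted = np.atleast_2d(coords) - point
    out = (
        shifted * math.cos(theta)
        + np.cross(np.broadcast_to(axis, shifted.shape), shifted) * math.sin(theta)
        + np.outer(shifted @ axis, axis) * (1 - math.cos(theta))
    )
    return out + point
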