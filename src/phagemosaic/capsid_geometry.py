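"""Icosahedral capsid lattice arithmetic.

A quasi-equivalent icosahedral capsid built on lattice indices (h, k) has
triangulation number T = h^2 + hk + k^2 and contains 60T subunits arranged
as 12 pentamers plus 10(T-1) hexamers.  In tailed phages one pentameric
vertex is replaced by the dodecameric portal, removing five capsid subunits,
so a virion carries 60T - 5 copies of the major capsid protein (775 for
T = 13).
"""

from __future__ import annotations


def t_number(h: int, k: int) -> int:
    """Triangulation number T = h^2 + hk + k^2 for lattice indices (h, k)."""
    if h < 0 or k < 0:
        raise ValueError("lattice indices must be non-negative")
    if h == 0 and k == 0:
        raise ValueError("(h, k) = (0, 0) is not a capsid lattice")
    return h * h + h * k + k * k


def enumerate_t(max_t: int) -> list[tuple[int, list[tuple[int, int]]]]:
    """All valid triangulation numbers <= max_t with canonical h >= k indices.

    Both chiral classes (h, k) and (k, h) describe the same T; only the
    h >= k representative is listed (plus the laevo partner when h != k).
    """
    if max_t < 1:
        raise ValueError("max_t must be >= 1")
    found: dict[int, list[tuple[int, int]]] = {}
    bound = int(max_t ** 0.5) + 1
    for h in range(bound + 1):
        for k in range(h + 1):
            if h == 0 and k == 0:
                continue
            t = t_number(h, k)
            if t <= max_t:
                found.setdefault(t, []).append((h, k))
    return sorted(found.items())


def is_valid_t(t: int) -> bool:
    return t >= 1 and any(tt == t for tt, _ in enumerate_t(t))


def subunit_count(t: int, portal_present: bool) -> int:
    """Copies of the capsid subunit: 60T, minus 5 when a portal replaces
    one pentameric vertex."""
    if not is_valid_t(t):
        raise ValueError(f"T={t} is not expressible as h^2+hk+k^2")
    return 60 * t - 5 if portal_present else 60 * t


def infer_t(copies: int, portal_present: bool) -> int:
    """Invert subunit_count: the T implied by a measured subunit copy number."""
    if copies < 55:
        raise ValueError("fewer than 55 subunits cannot tile an icosahedron")
    total = copies + 5 if portal_present else copies
    if total % 60 != 0:
        lo = (total // 60) * 60
        near = [lo - (5 if portal_present else 0), lo + 60 - (5 if portal_present else 0)]
        raise ValueError(f"{copies} copies is not 60T{'-5' if portal_present else ''} "
                         f"for any integer T; nearest valid counts: {near}")
    t = total // 60
    if not is_valid_t(t):
        raise ValueError(f"T={t} is not a valid triangulation number")
    return t


def capsid_report(t: int, portal_present: bool = True) -> dict:
    """Summary used by the CLI: T, lattice index candidates, copy numbers."""
    reps = dict(enumerate_t(t)).get(t)
    if reps is None:
        raise ValueError(f"T={t} is not a valid triangulation number")
    hk = []
    for (h, k) in reps:
        hk.append([h, k])
        if h != k:
            hk.append([k, h])  # the other chiral class
    return {
        "T": t,
        "hk_candidates": hk,
        "subunits_total": subunit_count(t, False),
        "subunits_virion": subunit_count(t, portal_present),
        "pentamers": 11 if portal_present else 12,
        "hexamers": 10 * (t - 1),
        "portal_present": portal_present,
    }
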