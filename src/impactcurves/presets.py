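"""Canonical scenario presets.

Shell presets cover the three model ecosystems spanning the water-chemistry
range in which dense mussel beds occur; macrophyte presets cross the three
model basins with an unproductive (3 ug/L) and a productive (30 ug/L)
pre-invasion chlorophyll level; designs presets are three landscape
configurations (equal/unequal type mixes, even/uneven abundance spacing)
that produce qualitatively different pooled cross-system curves from the
same three within-system lines.
"""

from __future__ import annotations

SHELL_PRESETS: dict[str, dict] = {
    "hardwater-lake": {"k_per_year": 0.05, "s0": 0.0, "years": 130},
    "moderately-hardwater-lake": {"k_per_year": 0.3, "s0": 0.0, "years": 130},
    "moderately-hardwater-river": {"k_per_year": 2.0, "s0": 0.0, "years": 130},
}

_BASINS = {
    "shallow": {"kind": "conical", "max_depth": 5.0},
    "deep": {"kind": "conical", "max_depth": 50.0},
    "shelf": {
        "kind": "shelf",
        "max_depth": 15.0,
        "shelf_top": 2.5,
        "shelf_bottom": 3.0,
        "shelf_area_fraction": 0.5,
    },
}
_CHL = {"unproductive": 3.0, "productive": 30.0}

MACROPHYTE_PRESETS: dict[str, dict] = {
    f"{basin}-{prod}": {"bathymetry": dict(bath), "chl_pre": chl}
    for basin, bath in _BASINS.items()
    for prod, chl in _CHL.items()
}

_THREE_SLOPES = {"slopes": [3.0, 1.0, 0.3], "labels": ["high", "moderate", "low"]}

DESIGNS_PRESETS: dict[str, dict] = {
    # equal numbers of each type, abundances evenly spaced within type
    "equal-even": {
        **_THREE_SLOPES,
        "proportions": [1 / 3, 1 / 3, 1 / 3],
        "n_lakes": 30,
        "abundance_mode": "even",
    },
    # equal numbers, abundances drawn from each lake's variable trajectory
    "equal-uneven": {
        **_THREE_SLOPES,
        "proportions": [1 / 3, 1 / 3, 1 / 3],
        "n_lakes": 30,
        "abundance_mode": "trajectory",
    },
    # unequal numbers of each type, abundances evenly spaced
    "unequal-even": {
        **_THREE_SLOPES,
        "proportions": [0.6, 0.3, 0.1],
        "n_lakes": 30,
        "abundance_mode": "even",
    },
}

PRESETS: dict[str, dict[str, dict]] = {
    "shell": SHELL_PRESETS,
    "macrophyte": MACROPHYTE_PRESETS,
    "designs": DESIGNS_PRESETS,
}
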