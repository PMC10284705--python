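"""Integer coding of tumour immune phenotypes (TIPs).

Per-day phenotypes are stored as small integers so that timelines can be
held in dense arrays, clustered and counted efficiently:

====  ==========  =========================================================
code  name        meaning
====  ==========  =========================================================
0     death       mouse euthanised/dead; all subsequent days are 0
1     desert      immune desert — few T cells anywhere in the lesion
2     excluded    immune excluded — T cells confined to the tumour rim
3     inflamed    immune inflamed — T cells infiltrate the tumour core
5     resolved    tumour rejected; all subsequent days are 5
====  ==========  =========================================================

``0`` and ``5`` are absorbing: once a timeline enters one of them it stays
there.  The canonical state order used for transition matrices places the
live phenotypes first, then the absorbing states.
"""

from __future__ import annotations

DEATH = 0
DESERT = 1
EXCLUDED = 2
INFLAMED = 3
RESOLVED = 5

#: canonical state order for transition matrices: desert, excluded,
#: inflamed, resolved, death
STATE_ORDER: tuple[int, ...] = (DESERT, EXCLUDED, INFLAMED, RESOLVED, DEATH)

#: absorbing phenotype codes
ABSORBING: frozenset[int] = frozenset({DEATH, RESOLVED})

STATE_NAMES: dict[int, str] = {
    DEATH: "death",
    DESERT: "desert",
    EXCLUDED: "excluded",
    INFLAMED: "inflamed",
    RESOLVED: "resolved",
}

NAME_TO_CODE: dict[str, int] = {v: k for k, v in STATE_NAMES.items()}


def validate_codes(codes) -> None:
    """Raise ``ValueError`` if any code is outside the state alphabet."""
    bad = set(int(c) for c in codes) - set(STATE_ORDER)
    if bad:
        raise ValueError(f"phenotype codes outside alphabet {sorted(STATE_ORDER)}: {sorted(bad)}")
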