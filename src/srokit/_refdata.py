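"""Loaders for the packaged reference data files.

Both data files are synthetic stand-ins (fixed-RNG sequences) whose
annotation geometry mirrors the published PARP-core fold landmarks and the
WWE/PARP/RST signature layout; see the ``description`` field inside each
JSON file.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("srokit.data").joinpath(name).open() as fh:
        return json.load(fh)


def fold_reference_raw() -> dict:
    """Raw fold-annotated PARP-core reference scaffold."""
    return _load("fold_reference.json")


def miniprofile_raw() -> dict:
    """Raw mini-profile consensus data (WWE, PARP_core, RST)."""
    return _load("miniprofiles.json")


def active_site_table() -> list[dict]:
    """Curated active-site reference rows (triad, loop, NAD, activity)."""
    return _load("active_sites.json")["rows"]
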