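"""Deterministic DICOM UID generation.

UIDs use the UUID-derived ``2.25.<decimal-uuid>`` form. The generator is
injectable and, when seeded, reproducible, so that fixtures and synthetic
cohorts serialise byte-identically across runs.
"""

from __future__ import annotations

import re
import uuid

import numpy as np

_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)*$")


def is_valid_uid(uid: str) -> bool:
    """Syntactic DICOM UID check: dotted decimal, components without leading
    zeros (single 0 allowed), at most 64 characters."""
    if not uid or len(uid) > 64 or not _UID_RE.match(uid):
        return False
    return all(c == "0" or not c.startswith("0") for c in uid.split("."))


class UIDGenerator:
    """Produces ``2.25.*`` UIDs; deterministic when constructed with a seed."""

    def __init__(self, seed: int | None = None):
        self._rng = np.random.default_rng(seed)

    def __call__(self) -> str:
        u = uuid.UUID(bytes=self._rng.bytes(16), version=4)
        return f"2.25.{u.int}"


_default = UIDGenerator()


def new_uid(generator: UIDGenerator | None = None) -> str:
    return (generator or _default)()
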