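"""Coded concepts: (value, scheme, meaning) triples from medical terminologies.

Every content-item name, code value, unit and segment label in this package is
a coded concept, typically drawn from SNOMED CT (designator ``SCT``), the DICOM
dictionary (``DCM``) or UCUM (``UCUM``). Two concepts are the same concept iff
their code value and coding-scheme designator agree; the meaning is display
text and never participates in equality or hashing.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CodedConcept:
    """A terminology code: ``(value, scheme, meaning)``.

    Parameters
    ----------
    value : str
        The code value, e.g. ``"87878005"``.
    scheme : str
        The coding-scheme designator, e.g. ``"SCT"``, ``"DCM"``, ``"UCUM"``.
    meaning : str
        Human-readable display text. Not part of concept identity.
    """

    value: str
    scheme: str
    meaning: str = field(compare=False)

    def __post_init__(self) -> None:
        if not self.value or not self.scheme:
            raise ValueError(
                "CodedConcept requires non-empty code value and coding scheme "
                f"(got value={self.value!r}, scheme={self.scheme!r})"
            )

    def __repr__(self) -> str:  # compact, log-friendly
        return f"({self.value}, {self.scheme}, {self.meaning!r})"


def code(value: str, scheme: str, meaning: str) -> CodedConcept:
    """Build a :class:`CodedConcept`; raises ``ValueError`` on empty value/scheme."""
    return CodedConcept(value, scheme, meaning)
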