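"""Exception hierarchy.

``CheckError`` carries the numeric id of the QC check that raised it so the
CLI can render "check 12: missing required columns ..." style messages.
"""

from __future__ import annotations


class SumstatsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SumstatsError):
    """Unreadable, undecidable, or malformed input file."""


class CheckError(SumstatsError):
    """Hard failure raised by a specific QC check."""

    def __init__(self, check_id: int, message: str):
        self.check_id = check_id
        super().__init__(f"check {check_id}: {message}")
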