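"""Exception and warning types raised across the processing chain.

Reader/parser failures are exceptions; measurement-quality problems are
never exceptions — they become :class:`~ankledyn.validation.ValidationReport`
codes so batch processing always completes.
"""


class AnkledynError(Exception):
    """Base class for all package-specific errors."""


# --- io_picoscope ---------------------------------------------------------

class EmptyBuffer(AnkledynError):
    """A buffer file contained a header but no data lines."""


class MalformedLine(AnkledynError):
    """A data line in a buffer file did not parse as a numeric pair."""

    def __init__(self, path, line_no, line):
        self.path = path
        self.line_no = line_no
        self.line = line
        super().__init__(f"{path}:{line_no}: not a numeric (time, voltage) pair: {line!r}")


class MissingBuffer(AnkledynError):
    """The two-digit buffer suffix sequence has a gap."""


class InconsistentBuffer(AnkledynError):
    """Buffers in one folder differ in sample count by more than one sample."""


class MissingDirection(AnkledynError):
    """Folder name carries neither a plantar- nor a dorsiflexion keyword."""


class MissingFoot(AnkledynError):
    """Folder name carries neither a left- nor a right-foot keyword."""


class AmbiguousKey(AnkledynError):
    """Conflicting folder-name keywords (e.g. both PFlex and Dorsi)."""


# --- filtering ------------------------------------------------------------

class UnstableDesign(AnkledynError):
    """Filter design produced a pole on or outside the unit circle."""


class NarrowBandWarning(UserWarning):
    """Sampling frequency is low enough that the rejection notch shifts
    away from the electric-network frequency; the filter should be
    redesigned."""


class FsMismatch(AnkledynError):
    """Recording and filter were designed for different sampling rates."""


# --- offset_detection -----------------------------------------------------

class EmptyWindow(AnkledynError):
    """No samples fall inside the offset-detection voltage window, so the
    offset level cannot be detected automatically."""


class NoBaselineSegments(AnkledynError):
    """Offset-stability assessment received no baseline intervals."""


# --- features -------------------------------------------------------------

class IndeterminateDirection(AnkledynError):
    """Positive and negative excursions about the offset differ by less
    than one ADC quantum; contraction direction cannot be inferred."""


class MissingCalibration(AnkledynError):
    """Torque output requested without a configured Nm/V gain."""


# --- synth ----------------------------------------------------------------

class ParamOutOfRange(AnkledynError):
    """Synthetic signal levels would clip the ADC full-scale range."""


class UnknownMode(AnkledynError):
    """Unrecognized error-injection mode tag."""


# --- cli ------------------------------------------------------------------

class NoMeasurements(AnkledynError):
    """Input root contains no measurement folders."""
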