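"""Exception hierarchy for scopeskill.

Every failure mode named in the module contracts maps to one exception
class here, so callers can catch either the broad :class:`ScopeSkillError`
or the precise condition.
"""


class ScopeSkillError(Exception):
    """Base class for all scopeskill errors."""


class ConfigError(ScopeSkillError):
    """Invalid or incomplete configuration block."""


# --- kinematics -----------------------------------------------------------

class DegenerateAxisError(ScopeSkillError):
    """Attachment point coincides with the fulcrum: shaft axis undefined."""


class RetractedToolError(ScopeSkillError):
    """Tool withdrawn past the fulcrum (insertion depth < 0)."""

    def __init__(self, depth_mm: float):
        self.depth_mm = depth_mm
        super().__init__(f"tool retracted past fulcrum (d = {depth_mm:.3f} mm)")


class UnreachableError(ScopeSkillError):
    """Required attachment point lies outside the 3R positioning workspace."""


# --- optics ---------------------------------------------------------------

class BehindCameraError(ScopeSkillError):
    """Point on or behind the image plane (depth <= near limit)."""


class NotVisibleError(ScopeSkillError):
    """Ring not visible: a boundary sample is behind the camera or outside
    the visibility cone."""


class ObliqueDegenerateError(ScopeSkillError):
    """Ring viewed at grazing incidence (< 5 deg to the ring plane)."""


# --- exercise / agents ----------------------------------------------------

class AgentStallError(ScopeSkillError):
    """Agent emitted no sample for more than 1 s of simulated time."""


# --- metrics / analysis ---------------------------------------------------

class EmptyLogError(ScopeSkillError):
    """Trial log contains no samples."""


class UnresolvableSampleError(ScopeSkillError):
    """A logged sample could not be resolved to a tip pose."""

    def __init__(self, index: int, reason: str = ""):
        self.index = index
        super().__init__(f"sample {index} unresolvable: {reason}")


class MissingTrialsError(ScopeSkillError):
    """Some subjects are missing trials required by a subset."""

    def __init__(self, subjects):
        self.subjects = list(subjects)
        super().__init__(f"subjects missing subset trials: {self.subjects}")


class ZeroVarianceError(ScopeSkillError):
    """A metric column is constant; correlation undefined."""


class NTooSmallError(ScopeSkillError):
    """Too few subjects (or rows) for the requested statistic."""


# --- io -------------------------------------------------------------------

class SchemaMismatchError(ScopeSkillError):
    """Session file schema version not supported by this reader."""


class MalformedLineError(ScopeSkillError):
    """Session file line could not be parsed."""

    def __init__(self, lineno: int, reason: str = ""):
        self.lineno = lineno
        super().__init__(f"malformed line {lineno}: {reason}")
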