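"""Exception hierarchy.

Every failure mode the toolkit can report deliberately (as opposed to
programming errors) derives from :class:`ZernipepError`, so callers can
catch one base class at CLI level.
"""


class ZernipepError(Exception):
    """Base class for all deliberate toolkit errors."""


class PDBParseError(ZernipepError):
    """A PDB/PQR line could not be parsed; message names the line number."""


class EmptyInputError(ZernipepError):
    """Input contained no usable records (e.g. zero ATOM lines)."""


class TopologyError(ZernipepError):
    """Trajectory models disagree on atom/residue composition."""


class ParameterLookupError(ZernipepError):
    """Force-field table misses one or more (residue, atom) entries."""

    def __init__(self, unresolved):
        self.unresolved = list(unresolved)
        super().__init__(
            "no parameter entry for: "
            + ", ".join(f"{res}/{atom}" for res, atom in self.unresolved)
        )


class MalformedResidueError(ZernipepError):
    """A residue is missing atoms required by the requested operation."""


class EmptyPatchError(ZernipepError):
    """No surface points fall inside the requested region."""


class DegenerateOrientationError(ZernipepError):
    """Patch mean normal is (numerically) zero; reorientation undefined."""


class SolverError(ZernipepError):
    """A numerical solver failed to bracket or converge."""


class ConfigurationError(ZernipepError):
    """A configuration value is out of its valid range."""


class SingularityError(ZernipepError):
    """Pairwise energy requested at zero separation."""


class AssignmentError(ZernipepError):
    """A surface point could not be attributed to any residue."""


class NoSegmentError(ZernipepError):
    """No residue exceeds the contact-occurrence threshold."""


class UndefinedFractionError(ZernipepError):
    """Energy-fraction denominator is zero."""


class CorrespondenceError(ZernipepError):
    """Atom selections of two structures cannot be put in 1:1 correspondence."""


class AdapterError(ZernipepError):
    """An external side-chain placer failed; diagnostics attached."""
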