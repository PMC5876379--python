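"""Exception hierarchy for the lipocontact pipeline."""


class LipocontactError(Exception):
    """Base class for all pipeline errors."""


class PDBParseError(LipocontactError):
    """A malformed ATOM/HETATM record; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class DuplicateAtomError(LipocontactError):
    """Two records share (chain, residue_id, atom name)."""


class SegmentMapError(LipocontactError):
    """A chain ID cannot be assigned to a segment."""


class ShapeError(LipocontactError):
    """Frame atom count does not match the topology."""


class SelectionSyntaxError(LipocontactError):
    """Invalid selection expression; carries the character position."""

    def __init__(self, position: int, message: str):
        self.position = position
        super().__init__(f"position {position}: {message}")


class GroupingError(LipocontactError):
    """Acyl-chain CH2/CH3 group assignment failed."""


class OverlappingSelectionError(LipocontactError):
    """Contact/energy selections share atoms."""


class MissingParameterError(LipocontactError):
    """No Lennard-Jones entry for (residue_name, atom_name)."""

    def __init__(self, residue_name: str, atom_name: str):
        self.residue_name = residue_name
        self.atom_name = atom_name
        super().__init__(
            f"no LJ parameters for atom {atom_name!r} in residue {residue_name!r}"
        )


class DegenerateFitError(LipocontactError):
    """Superposition fit set is too small or collinear."""


class InfeasibleGeometryError(LipocontactError):
    """Synthetic receptor geometry cannot host the ligand."""


class FrozenChainError(LipocontactError):
    """Monte-Carlo sampler exhausted its attempt budget with no accepted move."""


class ConfigError(LipocontactError):
    """Run configuration failed validation."""
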