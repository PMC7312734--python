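"""Exception hierarchy for the ppiwave pipeline."""


class PPIWaveError(Exception):
    """Base class for all ppiwave errors."""


class InvalidInputError(PPIWaveError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PPIWaveError, ValueError):
    """Input is structurally valid but mathematically degenerate
    (e.g. a constant property column, a zero pKa sum)."""


class InvalidResidueError(InvalidInputError):
    """A sequence character is outside the 20-letter amino-acid alphabet."""

    def __init__(self, residue: str, position: int, protein_id: str | None = None):
        self.residue = residue
        self.position = position
        self.protein_id = protein_id
        where = f" in {protein_id!r}" if protein_id else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}"
        )


class SequenceTooShortError(InvalidInputError):
    """Signal too short for the requested wavelet decomposition depth."""


class UndefinedAUCError(InvalidInputError):
    """AUC requested with only one class present."""


class ConfigError(PPIWaveError, ValueError):
    """Invalid model or run configuration."""


class DivergenceError(PPIWaveError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite loss {loss!r} at epoch {epoch}")


class ParseError(PPIWaveError, ValueError):
    """Malformed input file."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class LeakageError(PPIWaveError, ValueError):
    """An operation reserved for training data was applied to a test split."""
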