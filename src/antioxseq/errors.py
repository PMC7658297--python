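"""Package-wide exception types."""


class AntioxseqError(Exception):
    """Base class for all errors raised by antioxseq."""


class FastaParseError(AntioxseqError):
    """A FASTA file could not be parsed."""


class SequenceValidationError(AntioxseqError):
    """A sequence contains residues outside the 20-letter standard alphabet."""


class FeatureCSVError(AntioxseqError):
    """A feature-matrix CSV is malformed."""


class ConfigError(AntioxseqError):
    """A run configuration failed validation.

    Collects all field-level problems so a user sees every mistake at once.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))
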