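"""Exception hierarchy for pzsearch."""


class PzsearchError(Exception):
    """Base class for all pzsearch errors."""


class FastaParseError(PzsearchError):
    """Malformed FASTA input."""


class AlphabetError(PzsearchError):
    """A residue outside the amino-acid alphabet was encountered in strict mode."""


class HitTableFormatError(PzsearchError):
    """A tabular hit file row could not be parsed."""


class ConfigError(PzsearchError):
    """Invalid configuration value (unknown matrix, bad namespace, ...)."""


class LimitError(PzsearchError):
    """A configured submission limit was exceeded."""


class ConsistencyError(PzsearchError):
    """Partial results cannot be merged (mismatched configs, duplicate subjects)."""
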