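"""Exception hierarchy shared across the pipeline."""


class TweetsurvError(Exception):
    """Base class for all package-specific errors."""


class TerminologyError(TweetsurvError):
    """Malformed terminology input (bad records, cycles)."""


class TerminologyLookupError(TerminologyError, KeyError):
    """A node id referenced in a traversal does not exist."""


class CorpusFormatError(TweetsurvError):
    """The corpus file is unusable (e.g. mostly malformed lines)."""


class POIFormatError(TweetsurvError):
    """A POI table is missing required columns."""


class ValidationError(TweetsurvError, ValueError):
    """An input value violates a documented precondition."""


class ContractViolation(TweetsurvError):
    """A pluggable component (tagger, concept identifier) broke its contract."""


class StaleMentionError(TweetsurvError):
    """A mention's span no longer matches the text it claims to index."""
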