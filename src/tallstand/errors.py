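"""Exception hierarchy."""


class TallstandError(Exception):
    """Base class for all package errors."""


class SchemaError(TallstandError):
    """A table is missing a mandatory column or holds an unparseable value."""


class DuplicateTagError(TallstandError):
    """A stem tag occurs more than once within a census."""

    def __init__(self, tags):
        self.tags = sorted(tags)
        super().__init__(f"duplicate stem tags: {', '.join(self.tags)}")


class ConfigError(TallstandError):
    """An allometry or generator configuration is invalid or incomplete."""


class EmptyCensusError(TallstandError):
    """An operation that needs stems received none."""


class UnclassifiedSpeciesError(TallstandError):
    """Censused species missing from the species-guild lookup."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"species without guild assignment: {', '.join(self.names)}")


class InsufficientDataError(TallstandError):
    """Too few observations to fit the requested model."""


class SingularDesignError(TallstandError):
    """The regression design matrix is rank deficient."""

    def __init__(self, predictors):
        self.predictors = list(predictors)
        super().__init__(
            "rank-deficient design; collinear predictors: " + ", ".join(self.predictors)
        )


class DegenerateEnvelopeError(TallstandError):
    """Climate-envelope reference points are too few or collinear."""
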