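"""Exception types shared across the package."""


class CooperError(Exception):
    """Base class for all otr-cooper errors."""


class InfeasibleLayoutError(CooperError):
    """An ordered set of staves cannot cover the head disc."""


class InfeasiblePoolError(CooperError):
    """A stave pool cannot seed a feasible head or body within the retry budget."""


class ExhaustedQueueError(CooperError):
    """The idle stave queue has fewer staves than the method dataset needs.

    Carries ``elements_completed`` so a production run can report how far it got.
    """

    def __init__(self, message: str, elements_completed: int = 0):
        super().__init__(message)
        self.elements_completed = elements_completed
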