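"""Exception hierarchy for neurostate."""


class NeurostateError(Exception):
    """Base class for all neurostate errors."""


class InputError(NeurostateError):
    """Malformed or inconsistent input data (shape, ordering, emptiness)."""


class ParameterError(NeurostateError):
    """A parameter outside its documented range."""


class NoEligibleComponentsError(NeurostateError):
    """No principal component met the correlation benchmark.

    Carries the largest |r| observed so callers can report how far the data
    fell short of the retention criterion.
    """

    def __init__(self, benchmark: float, max_abs_r: float):
        self.benchmark = benchmark
        self.max_abs_r = max_abs_r
        super().__init__(
            f"no eligible components: max |r| = {max_abs_r:.4g} "
            f"below benchmark {benchmark:.4g}"
        )
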