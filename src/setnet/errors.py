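"""Exception types shared across the package."""


class DataError(ValueError):
    """Malformed or inconsistent user data (bad file row, empty symbol, ...).

    The command-line interface maps this to exit code 1; usage errors
    (unknown flags, missing required options) exit with 2.
    """
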