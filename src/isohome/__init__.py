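"""isohome: geomagnetic isoline drift, odor-plume dispersal, and dual-cue
island-finding simulations for natal-homing marine animals."""

from importlib import resources

__version__ = "0.1.0"

__all__ = ["vendored_coefficients_path", "__version__"]


def vendored_coefficients_path():
    """Path to the bundled early-epoch main-field coefficient table."""
    return resources.files("isohome").joinpath("data/igrf_early_epochs.txt")
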