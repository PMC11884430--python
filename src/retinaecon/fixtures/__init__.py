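"""Frozen synthetic example scenarios (one DME-like, one nAMD-like).

Both files were emitted by :func:`retinaecon.synthetic.generate_parameter_set`
with fixed seeds; they contain no trial-derived numbers and exist so that
examples, tests and reports have a stable, human-readable input to share.
"""

from importlib import resources

from ..parameters import ParameterSet, load_parameter_set

__all__ = ["load_example"]


def load_example(disease: str = "DME") -> ParameterSet:
    """Load the frozen synthetic scenario for ``disease`` ("DME" or "nAMD")."""
    name = f"{disease.lower()}_synthetic.yaml"
    ref = resources.files(__package__) / name
    with resources.as_file(ref) as path:
        return load_parameter_set(str(path))
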