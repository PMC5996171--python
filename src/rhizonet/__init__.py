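"""rhizonet: multi-kingdom co-occurrence networks and hub taxa for
soil/rhizosphere/root amplicon microbiome surveys."""

from . import cooccurrence, diversity, feature_table, hubnet, synthetic_data

__version__ = "0.1.0"

__all__ = [
    "cooccurrence",
    "diversity",
    "evaluation",
    "feature_table",
    "hubnet",
    "pipeline",
    "synthetic_data",
    "__version__",
]


def __getattr__(name):
    # pipeline/evaluation import optional heavier deps lazily
    if name in ("pipeline", "evaluation"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
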