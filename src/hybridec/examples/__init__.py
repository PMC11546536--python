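"""Shipped example inputs."""

from pathlib import Path

__all__ = ["sma_graph_path"]


def sma_graph_path() -> Path:
    """Path of the example motor-function selection-graph edge list."""
    return Path(__file__).parent / "sma_selection_graph.txt"
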