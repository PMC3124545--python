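"""wingshape: geometric morphometrics and parsimony phylogenetics of
2-D landmark data, with tools to compare the two distance structures.

The package covers the full workflow of a landmark-based evolutionary
study: Procrustes superimposition and tangent-space checks, thin-plate
spline relative warps, per-group metric disparity, UPGMA phenograms,
Fitch maximum parsimony with CI/RI/bootstrap/consensus, squared-change
parsimony ancestral shapes, and Mantel matrix-correspondence tests —
plus a seeded synthetic-data generator for end-to-end validation.
"""

from . import (ancestral, cladistics, disparity, formats, phenetics,
               pipeline, superimposition, synthetic, treecompare, trees,
               warps)

__version__ = "0.1.0"

__all__ = [
    "ancestral", "cladistics", "disparity", "formats", "phenetics",
    "pipeline", "plotting", "superimposition", "synthetic", "treecompare",
    "trees", "warps", "__version__",
]


def __getattr__(name):
    # plotting pulls in matplotlib; import it lazily
    if name == "plotting":
        from . import plotting
        return plotting
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
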