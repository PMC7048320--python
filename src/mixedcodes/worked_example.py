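"""The K=3, n=2 worked-example codebooks, laid out for bit-for-bit printing.

Three binary features give eight stimuli, written 1-based (111, 211, ...,
222).  The three codes of order 1, 2, and 3 use 6, 12, and 8 units.  The
order-2 layout groups units into the feature-pair blocks (f1,f2), (f2,f3),
(f1,f3), and within each block the first listed feature's value varies
fastest; the canonical :func:`mixedcodes.codes.build_codebook` layout
(lexicographic subsets and value combinations) encodes the same geometry
with the columns permuted.
"""

from __future__ import annotations

from .codes import Codebook, CodeSpec, StimulusSpace, build_codebook

_SUBSETS = {
    1: [(0,), (1,), (2,)],
    2: [(0, 1), (1, 2), (0, 2)],
    3: [(0, 1, 2)],
}


def worked_example_codebooks(energy_variant: str = "variance") -> dict[int, Codebook]:
    """The order-1, -2, and -3 codebooks for K=3 binary features."""
    space = StimulusSpace(3, 2)
    books = {}
    for order, subsets in _SUBSETS.items():
        books[order] = build_codebook(
            space,
            CodeSpec(order, energy_variant=energy_variant),
            feature_subsets=subsets,
            value_order="colex",
        )
    return books


def stimulus_label(stimulus) -> str:
    """1-based compact label for a stimulus, e.g. (1, 0, 0) -> '211'."""
    return "".join(str(v + 1) for v in stimulus)


def format_rows(codebook: Codebook) -> list[str]:
    """Rows of the codebook as printable 'label  b b b ...' strings."""
    lines = []
    for stim, word in zip(codebook.space.stimuli(), codebook.words):
        bits = " ".join(str(int(b)) for b in word)
        lines.append(f"{stimulus_label(stim)}  {bits}")
    return lines
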