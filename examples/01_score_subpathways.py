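"""Score sub-pathways of a toy five-gene pathway by hand.

Builds a small pathway, assigns per-gene z-scores directly, and prints the
degree-weighted Stouffer score z(Q) for several edge subsets.  The score is
standard normal under an iid-normal null for ANY fixed subset, so the values
are directly comparable between subgraphs of different sizes and shapes —
and the full pathway does not necessarily score highest.
"""

from subpert import Pathway, perturbation_score

pathway = Pathway.from_edges(
    "toy", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
)
z = {"A": 3.0, "B": 2.5, "C": 0.2, "D": -0.5, "E": 0.1}

subsets = {
    "A-B only": [("A", "B")],
    "A-B, B-C": [("A", "B"), ("B", "C")],
    "full pathway": sorted(pathway.interactions),
}
for name, edges in subsets.items():
    print(f"{name:14s} z(Q) = {perturbation_score(edges, z):+.4f}")

# The strongly perturbed end of the path (genes A, B) scores higher alone
# than the whole pathway: diluting a perturbed core with unperturbed genes
# lowers the combined evidence.
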