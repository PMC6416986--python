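"""Classify every cytosine of a small genome into CG / CHG / CHH.

Plant methylomes are summarized per sequence context (H = A, C or T);
context composition is the denominator for every downstream methylation
statistic.
"""

from dmrkit import Genome, context_frequencies, enumerate_sites

genome = Genome(
    sequences={"Chr1": "ACGTCCGGCATACGGATCCTAGGCAT", "ChrC": "ACGTACGT"},
    chloroplast_name="ChrC",
)
sites = enumerate_sites(genome)
print(sites.to_string(index=False))
print()
freqs = context_frequencies(sites)
print("context frequencies:", freqs)
print(
    "Each row is one strand-resolved cytosine; the frequencies count sites "
    "per context (UNKNOWN = the downstream bases needed for the call are "
    "missing or N)."
)
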