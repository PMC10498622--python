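"""Convert a peptide between the three supported line notations.

BILN is the native format: monomers joined by '-', chains by '.', and
paired (n,i) annotations marking extra bonds through numbered R-groups.
HELM carries the same information in polymer/connection sections; FASTA
carries only the plain sequence of natural residues.
"""

from pepkit import biln_to_helm, fasta_to_biln, helm_to_biln

biln = "C(1,3)-A-A-A-C(1,3)"
helm = biln_to_helm(biln)
print(f"BILN : {biln}")
print(f"HELM : {helm}")
print(f"back : {helm_to_biln(helm)}")
# The (1,3) pair says both cysteines take part in bond 1 through their
# R3 side-chain thiols: a disulfide-closed macrocycle.

print(f"FASTA 'CAAAC' -> {fasta_to_biln('CAAAC')}")
# FASTA has no way to state the disulfide, so the converted chain is
# linear: cyclization information only exists in BILN/HELM.
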