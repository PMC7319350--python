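# Example group-label file for the structure survey.  These PDB entries are
# SPOUT-class (trefoil-knotted) methyltransferases; download the structures
# yourself and pair them with this file.  Knot detection is out of scope here:
# group labels are always user-supplied metadata.
structure_id	group
1uak	knotted
1x7p	knotted
2egv	knotted
2v3k	knotted
3nk7	knotted
4fak	knotted
4yvg	knotted
5h5f	knotted
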