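# Synthetic surrogate hERG alert set for benchmarking the expert-fallback
# ensemble. Five hand-written SMARTS riffing on the classic hERG
# pharmacophore (a basic amine a few rotatable bonds from an aromatic or
# lipophilic anchor). Not derived from any proprietary knowledge base.
name	smarts	rationale
dialkylamino_group	[NX3;H0;!$(N-[!#6;!#1]);!$(N-C=O)](-[CH3])-[CH3]	N,N-dimethyl basic amine, the prototypical hERG cation site
basic_amine_ethyl_aryl	[NX3;!$(N-[!#6;!#1]);!$(N-C=O)]-[CX4]-[CX4]-[c]	basic nitrogen two saturated bonds from an aromatic ring
basic_amine_propyl_aryl	[NX3;!$(N-[!#6;!#1]);!$(N-C=O)]-[CX4]-[CX4]-[CX4]-[c]	basic nitrogen three saturated bonds from an aromatic ring
cyclic_amine_linker	[#7X3;R;!$(N-C=O);!$(N-[!#6;!#1])]-[CX4]-[CX4]	alicyclic amine (piperidine/piperazine-like) with an alkyl linker
lipophilic_amine_chain	[NX3;!$(N-[!#6;!#1]);!$(N-C=O)]-[CX4]-[CX4]-[CX4]-[CX4]	basic amine on an extended lipophilic chain
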