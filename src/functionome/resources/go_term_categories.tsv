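term_id	name	category
GO:0002682	regulation of immune system process	immune_inflammatory
GO:0002520	immune system development	immune_inflammatory
GO:0002252	immune effector process	immune_inflammatory
GO:0006811	ion transport	membrane_transporter
GO:0005215	transporter activity	membrane_transporter
GO:0051049	regulation of transport	membrane_transporter
GO:0040011	locomotion	membrane_transporter
GO:0046903	secretion	membrane_transporter
GO:0022610	biological adhesion	membrane_transporter
GO:0055085	transmembrane transport	membrane_transporter
GO:0070727	cellular macromolecule localization	membrane_transporter
GO:0046907	intracellular transport	membrane_transporter
GO:0001775	cell activation	cell_cycle_signaling
GO:0045595	regulation of cell differentiation	cell_cycle_signaling
GO:0001816	cytokine production	cell_cycle_signaling
GO:0042592	homeostatic process	cell_cycle_signaling
GO:0051240	positive regulation of multicellular organismal process	cell_cycle_signaling
GO:0007267	cell-cell signaling	cell_cycle_signaling
GO:0048585	negative regulation of response to stimulus	cell_cycle_signaling
GO:0051276	chromosome organization	cell_cycle_signaling
GO:0006915	apoptotic process	cell_cycle_signaling
GO:0007049	cell cycle	cell_cycle_signaling
GO:0033043	regulation of organelle organization	cell_cycle_signaling
GO:0023056	positive regulation of signaling	cell_cycle_signaling
GO:0051241	negative regulation of multicellular organismal process	cell_cycle_signaling
GO:0005102	signaling receptor binding	cell_cycle_signaling
GO:0080134	regulation of response to stress	cell_cycle_signaling
GO:0009719	response to endogenous stimulus	cell_cycle_signaling
GO:0044281	small molecule metabolic process	cell_metabolism
GO:0006629	lipid metabolic process	cell_metabolism
GO:0031399	regulation of protein modification process	cell_metabolism
GO:0016070	RNA metabolic process	cell_metabolism
GO:0051174	regulation of phosphorus metabolic process	cell_metabolism
GO:0019219	regulation of nucleobase-containing compound metabolic process	cell_metabolism
GO:0006259	DNA metabolic process	cell_metabolism
GO:0006468	protein phosphorylation	cell_metabolism
GO:0018193	peptidyl-amino acid modification	cell_metabolism
GO:0060429	epithelium development	others
GO:0022008	neurogenesis	others
GO:0000003	reproduction	others
GO:0044419	interspecies interaction between organisms	others
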