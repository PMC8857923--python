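species	mean_cpg_oe_nonortholog	mean_cpg_oe_tenway_ortholog	t_stat	p_value
Acropora digitifera	0.7093909	0.6666281	15.794	2.2e-16
Aiptasia pallida	0.7152435	0.6313672	27.393	2.2e-16
Alatina alata	0.7597698	0.7381270	11.037	2.2e-16
Aurelia coerulia	0.6475442	0.6267479	6.8606	7.135e-12
Calvadosia cruxmelitensis	0.7769339	0.8065653	-15.144	2.2e-16
Clytia hemisphaerica	0.8164449	0.8091184	3.2878	0.001012
Hydra vulgaris	0.6437276	0.6156787	8.1367	4.315e-16
Morbakka virulenta	0.6508604	0.6392557	5.6923	1.271e-08
Nematostella vectensis	0.7860412	0.7203910	25.841	2.2e-16
Physalia physalis	0.7628115	0.6970781	16.648	2.2e-16
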