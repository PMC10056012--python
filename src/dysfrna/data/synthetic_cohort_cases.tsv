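case_id	pre_study_state	n_plp_post	phase_post	other_gene_dx
S001	two_PLP	2	trans	0
S002	two_PLP	2	trans	0
S003	two_PLP	2	trans	0
S004	two_PLP	2	trans	0
S005	two_PLP	2	trans	0
S006	two_PLP	2	trans	0
S007	two_PLP	2	trans	0
S008	two_PLP	2	trans	0
S009	two_PLP	2	trans	0
S010	two_PLP	2	trans	0
S011	two_PLP	2	trans	0
S012	two_PLP	2	trans	0
S013	two_PLP	2	trans	0
S014	two_PLP	2	trans	0
S015	two_PLP	2	trans	0
S016	two_PLP	2	trans	0
S017	two_PLP	2	trans	0
S018	two_PLP	2	trans	0
S019	two_PLP	2	trans	0
S020	two_PLP	2	trans	0
S021	two_PLP	2	hom	0
S022	two_PLP	2	hom	0
S023	two_PLP	2	hom	0
S024	two_PLP	2	hom	0
S025	one_PLP	2	trans	0
S026	one_PLP	2	trans	0
S027	one_PLP	2	trans	0
S028	one_PLP	2	trans	0
S029	one_PLP	2	trans	0
S030	one_PLP	2	trans	0
S031	one_PLP	2	trans	0
S032	one_PLP	2	trans	0
S033	one_PLP	2	trans	0
S034	one_PLP	2	trans	0
S035	one_PLP	2	trans	0
S036	one_PLP	2	trans	0
S037	one_PLP	2	trans	0
S038	one_PLP	2	trans	0
S039	one_PLP	2	trans	0
S040	one_PLP	2	trans	0
S041	one_PLP	2	trans	0
S042	one_PLP	2	trans	0
S043	one_PLP	2	trans	0
S044	one_PLP	2	trans	0
S045	one_PLP	2	trans	0
S046	one_PLP	2	trans	0
S047	one_PLP	2	trans	0
S048	one_PLP	2	trans	0
S049	one_PLP	2	trans	0
S050	one_PLP	2	trans	0
S051	one_PLP	2	hom	0
S052	one_PLP	2	hom	0
S053	one_PLP	2	hom	0
S054	one_PLP	2	hom	0
S055	one_PLP	1	unknown	0
S056	one_PLP	1	unknown	0
S057	one_PLP	1	unknown	0
S058	one_PLP	1	unknown	0
S059	VUS_or_conflicting_only	2	trans	0
S060	VUS_or_conflicting_only	2	trans	0
S061	VUS_or_conflicting_only	2	trans	0
S062	VUS_or_conflicting_only	2	trans	0
S063	VUS_or_conflicting_only	2	trans	0
S064	VUS_or_conflicting_only	2	trans	0
S065	VUS_or_conflicting_only	0	unknown	1
S066	VUS_or_conflicting_only	1	unknown	0
S067	VUS_or_conflicting_only	1	unknown	0
S068	VUS_or_conflicting_only	1	unknown	0
S069	VUS_or_conflicting_only	1	unknown	0
S070	VUS_or_conflicting_only	1	unknown	0
S071	VUS_or_conflicting_only	1	unknown	0
S072	VUS_or_conflicting_only	0	unknown	0
S073	VUS_or_conflicting_only	0	unknown	0
S074	VUS_or_conflicting_only	0	unknown	0
S075	VUS_or_conflicting_only	0	unknown	0
S076	VUS_or_conflicting_only	0	unknown	0
S077	VUS_or_conflicting_only	0	unknown	0
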