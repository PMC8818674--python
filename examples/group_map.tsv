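accession	functional_group
ACC00001	carbohydrate metabolism
ACC00002	secondary metabolism
ACC00003	defense response
ACC00004	translation
ACC00005	carbohydrate metabolism
ACC00006	secondary metabolism
ACC00007	defense response
ACC00008	translation
ACC00009	carbohydrate metabolism
ACC00010	secondary metabolism
ACC00011	defense response
ACC00012	translation
ACC00013	carbohydrate metabolism
ACC00014	secondary metabolism
ACC00015	defense response
ACC00016	translation
ACC00017	carbohydrate metabolism
ACC00018	secondary metabolism
ACC00019	defense response
ACC00020	translation
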