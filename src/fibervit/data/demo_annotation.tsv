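feature_id	vitamin	role	note
EC 2.5.1.3	B1	S	thiamine phosphate synthase
EC 2.7.6.2	B1	S	thiamine pyrophosphokinase; produces TPP, the form absorbed through the colonic TPP transporter, so classified upstream
EC 2.2.1.1	B1	D	transketolase, TPP-dependent
EC 1.2.4.1	B1	D	pyruvate dehydrogenase E1, TPP-dependent
ThiT_transporter	B1	T	thiamine ECF transporter substrate-binding protein
EC 2.5.1.9	B2	S	riboflavin synthase
EC 3.5.4.26	B2	S	diaminohydroxyphosphoribosylaminopyrimidine deaminase
EC 2.7.1.26	B2	D	riboflavin kinase, converts riboflavin to FMN
EC 2.7.7.2	B2	D	FAD synthetase
EC 1.4.3.16	B3	S	L-aspartate oxidase
EC 2.5.1.72	B3	S	quinolinate synthase
EC 2.4.2.11	B3	D	nicotinate phosphoribosyltransferase, consumes nicotinate
EC 6.3.4.21	B3	D	nicotinate phosphoribosyltransferase (NadV-type salvage)
EC 6.3.2.1	B5	S	pantothenate synthetase
EC 2.7.1.33	B5	S	pantothenate kinase; bacterial kinase kept upstream because host lumenal phosphatases readily dephosphorylate the product
EC 6.3.2.5	B5	D	phosphopantothenate-cysteine ligase, toward CoA
EC 2.7.7.3	B5	D	pantetheine-phosphate adenylyltransferase, toward CoA
EC 2.6.99.2	B6	S	pyridoxine 5'-phosphate synthase
EC 1.4.3.5	B6	S	pyridoxamine 5'-phosphate oxidase
EC 2.7.1.35	B6	S	pyridoxal kinase; bacterial kinase kept upstream because host lumenal phosphatases readily dephosphorylate the product
EC 2.6.1.52	B6	D	phosphoserine aminotransferase, PLP-dependent consumer
EC 2.8.1.6	B7	S	biotin synthase
EC 6.3.3.3	B7	S	dethiobiotin synthase
EC 6.3.4.15	B7	D	biotin--protein ligase, consumes biotin
EC 6.4.1.2	B7	D	acetyl-CoA carboxylase, biotin-dependent
EC 2.5.1.15	B9	S	dihydropteroate synthase
EC 6.3.2.17	B9	S	dihydrofolate synthase
EC 6.3.4.3	B9	D	formate--tetrahydrofolate ligase, consumes THF
EC 2.1.2.1	B9	D	serine hydroxymethyltransferase, THF-dependent
EC 6.6.1.2	B12	S	cobaltochelatase
EC 2.7.8.26	B12	S	adenosylcobinamide-GDP ribazoletransferase (CobS)
EC 2.1.1.13	B12	D	methionine synthase, cobalamin-dependent
EC 5.4.99.2	B12	D	methylmalonyl-CoA mutase, cobalamin-dependent
BtuB_transporter	B12	T	outer-membrane cobalamin transporter
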