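hlgt	soc	n11_elderly	prr_elderly	chi2_elderly	sv_elderly	n11_non_elderly	prr_non_elderly	chi2_non_elderly	sv_non_elderly	non_elderly_corrected	published_flag
Deliria (include confusion)	Psychiatric disorders	84	16.2	1079.4	9.8	34	12.0	304.3	8.2	0	0
Product use issues	Injury poisoning and procedural complications	14	40.0	391.1	9.7	31	23.0	536.5	9.4	0	0
Sleep disturbances (include subtypes)	Nervous system disorders	26	14.9	294.4	8.4	14	6.8	60.9	6.0	0	0
Sleep disturbances	Psychiatric disorders	38	10.8	309.3	8.1	24	6.0	91.0	6.3	0	0
Glaucoma and ocular hypertension	Eye disorders	10	21.3	152.6	8.1	0	1.6	0.3	-0.7	1	1
Psychiatric and behavioural symptoms NEC	Psychiatric disorders	22	13.7	225.8	8.0	24	4.4	58.7	5.6	0	0
Impulse control disorders NEC	Psychiatric disorders	6	26.0	102.5	7.9	0	1.0	0.5	-0.7	1	1
Dementia and amnestic conditions	Psychiatric disorders	21	10.0	152.3	7.3	13	14.4	134.5	7.6	0	0
Suicidal and self-injurious behaviours NEC	Psychiatric disorders	19	10.4	142.0	7.3	49	7.3	250.1	7.5	0	0
Mental impairment disorders	Nervous system disorders	22	8.3	127.8	7.0	14	10.1	98.4	6.9	0	0
Neurological disorders NEC	Nervous system disorders	153	3.6	294.5	7.0	103	3.6	194.7	6.5	0	0
Neurological special senses and psychiatric investigations	Investigations	6	13.4	52.2	6.5	1	2.1	0.0007	-6.5	0	1
Psychiatric disorders NEC	Psychiatric disorders	39	4.0	83.1	5.8	50	6.1	203.1	7.1	0	0
Respiratory disorders NEC	Respiratory thoracic and mediastinal disorders	51	2.9	60.8	5.2	35	2.7	36.1	4.6	0	0
Injuries by physical agents	Injury poisoning and procedural complications	7	6.4	25.6	5.1	2	1.2	0.008	-4.6	0	1
Personality disorders and disturbances in behavior	Psychiatric disorders	5	7.6	21.3	5.1	3	1.9	0.6	0.1	0	1
Neurological disorders of the eye	Nervous system disorders	9	4.6	21.3	4.6	4	2.4	2.0	1.6	0	1
Injuries NEC	Injury poisoning and procedural complications	35	2.6	33.0	4.5	17	2.6	15.4	3.7	0	0
Changes in physical activity	Psychiatric disorders	6	4.9	14.7	4.3	4	2.8	3.0	2.2	0	0
Manic and bipolar mood disorders and disturbances	Psychiatric disorders	3	6.7	9.0	4.1	2	1.2	0.02	-3.8	0	1
Movement disorders (include parkinsonism)	Nervous system disorders	21	2.7	19.9	4.0	12	1.6	2.1	1.2	0	1
Anxiety disorders and symptoms	Psychiatric disorders	6	3.7	9.0	3.5	7	2.1	3.0	1.8	0	0
Therapeutic and nontherapeutic effects (exclude toxicity)	General disorders and administration site conditions	15	2.6	12.7	3.5	16	3.0	19.1	4.1	0	0
Enzyme investigations NEC	Investigations	17	2.4	12.4	3.4	3	0.4	2.1	-0.2	0	1
Disturbances in thinking and perception	Psychiatric disorders	12	2.5	9.1	3.1	5	1.2	0.05	-2.9	0	1
Vision disorders	Eye disorders	7	2.6	5.3	2.6	3	1.6	0.2	-0.9	0	1
Ocular infections irritations and inflammations	Eye disorders	8	2.4	5.0	2.5	0	0.1	2.9	-1.2	1	1
Depressed mood disorders and disturbances	Psychiatric disorders	5	2.8	4.1	2.4	6	2.5	3.9	2.3	0	0
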