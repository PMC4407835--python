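icd9_code	concept_id
349.9	23853001
204.00	91857003
204.01	91857003
205.00	91861009
205.01	91861009
205.10	92818009
204.10	92814006
202.80	118600007
201.90	118599009
202.00	1929004
200.10	404150006
200.11	404151005
203.00	109989006
170.9	38661007
170.8	307576001
194.0	302849000
189.0	302845006
171.9	409016009
191.6	443936004
191.9	424413001
191.8	1157170009
191.7	277505007
190.5	371973000
155.0	400003003
157.9	363418001
183.0	363443007
186.9	399068003
186.0	254938000
200.60	255052006
200.20	128875000
208.90	93143009
199.1	128462008
285.9	271737000
287.5	302215000
288.00	165517008
780.60	386661006
786.09	271825005
787.02	422587007
787.03	422400008
784.0	25064002
780.39	91175000
780.79	13791008
783.21	161832001
780.96	367391008
599.70	405729008
782.1	271807003
787.91	62315008
789.00	21522001
785.6	30746006
789.1	80515008
789.2	16294009
570	59927004
586	42399005
428.0	84114007
042	86406008
070.30	66071002
070.51	128241005
070.9	40468003
011.90	56717001
V22.2	77386006
250.00	73211009
401.9	38341003
493.90	195967001
345.90	84757009
311	35489007
300.00	197480006
780.2	271594007
244.9	40930008
593.9	90708001
573.9	235856003
429.9	56265001
199.0	363346000
199.2	255328000
758.0	17971005
305.1	110483000
305.00	228273003
798.9	419099009
208.00	726721002
692.82	403946000
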