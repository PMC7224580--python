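point	theta1	theta2	theta3	theta4	theta5	theta6	theta7	theta8
1	7.239380624	0.1047069812	0.1045129736	1.114909161	2.017259480	0.1057288524	2.544613812	0.1021803160
2	4.684802750	0.5200773771	1.589343505	0.1804775460	0.1270218587	0.1129848293	0.1816907000	5.708851611
3	6.865206499	0.2105440222	0.2524064999	0.1025041753	0.1178107732	0.1017610135	0.4495453146	5.796119139
4	4.885859541	0.4985163876	0.7212641184	2.119877596	0.1655484166	0.1246565927	0.7180476375	8.912153306
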