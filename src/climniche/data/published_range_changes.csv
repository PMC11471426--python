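species,current,future,loss,gain,maintain,percent_lost,percent_gained,range_change
Sceloporus arenicolus,4322,0,4322,0,0,100.00,0.00,-100.00
Phrynosoma douglasii,188650,4897,184792,1039,3858,97.96,0.55,-97.40
Anniella pulchra,28923,3722,25896,695,3027,89.53,2.40,-87.13
Thamnophis couchii,76300,18958,58877,1535,17423,77.17,2.01,-75.15
Aspidoscelis flagellicauda,36205,10057,31429,5281,4776,86.81,14.59,-72.22
Sceloporus virgatus,22963,6606,21362,5005,1601,93.03,21.80,-71.23
Crotalus pricei,46652,17456,38514,9318,8138,82.56,19.97,-62.58
Crotalus willardi,21943,8226,19176,5459,2767,87.39,24.88,-62.51
Sceloporus jarrovii,178006,68042,133645,23681,44361,75.08,13.30,-61.78
Sceloporus slevini,25788,12126,22968,9306,2820,89.07,36.09,-52.98
Aspidoscelis uniparens,70471,33148,64910,27587,5561,92.11,39.15,-52.96
Crotalus lepidus,130401,63573,93115,26287,37286,71.41,20.16,-51.25
Sceloporus graciosus,458409,245176,367842,154609,90567,80.24,33.73,-46.52
Charina bottae,440424,248029,339587,147192,100837,77.11,33.42,-43.68
Crotalus molossus,321340,230966,190524,100150,130816,59.29,31.17,-28.12
Aspidoscelis sonorae,47145,36709,26835,16399,20310,56.92,34.78,-22.14
Senticolis triaspis,86733,69096,67975,50338,18758,78.37,58.04,-20.34
Phrynosoma mcallii,15033,12475,13200,10642,1833,87.81,70.79,-17.02
Elgaria kingii,115286,96979,65054,46747,50232,56.43,40.55,-15.88
Lampropeltis splendida,119582,106743,81925,69086,37657,68.51,57.77,-10.74
Coluber constrictor,454753,406524,309533,261304,145220,68.07,57.46,-10.61
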