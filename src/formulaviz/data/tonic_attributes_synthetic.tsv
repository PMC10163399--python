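herb	cold	hot	warm	cool	calm	pungent	sweet	sour	bitter	salty	tasteless	astringent	liver	heart	spleen	lung	kidney	bladder	large_intestine	small_intestine	stomach	gallbladder	pericardium
Renshen	0	0	1	0	0	0	1	0	1	0	0	0	0	1	1	1	1	0	0	0	0	0	0
Shudihuang	0	0	1	0	0	0	1	0	0	0	0	0	1	0	0	0	1	0	0	0	0	0	0
Danggui	0	0	1	0	0	1	1	0	0	0	0	0	1	1	1	0	0	0	0	0	0	0	0
Chuanxiong	0	0	1	0	0	1	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	1	1
Baizhu	0	0	1	0	0	0	1	0	1	0	0	0	0	0	1	0	0	0	0	0	1	0	0
Fuling	0	0	0	0	1	0	1	0	0	0	1	0	0	1	1	1	1	0	0	0	0	0	0
Baishao	1	0	0	0	0	0	0	1	1	0	0	0	1	0	1	0	0	0	0	0	0	0	0
Zhigancao	0	0	0	0	1	0	1	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0
Shengjiang	0	0	1	0	0	1	0	0	0	0	0	0	0	0	1	1	0	0	0	0	1	0	0
Dazao	0	0	1	0	0	0	1	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0
Lianzi	0	0	0	0	1	0	1	0	0	0	0	1	0	1	1	0	1	0	0	0	0	0	0
Yiyiren	0	0	0	1	0	0	1	0	0	0	1	0	0	0	1	1	0	0	0	0	1	0	0
Shanyao	0	0	0	0	1	0	1	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	0
Jiegeng	0	0	0	0	1	1	0	0	1	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Gancao	0	0	0	0	1	0	1	0	0	0	0	0	0	1	1	1	0	0	0	0	1	0	0
Sharen	0	0	1	0	0	1	0	0	0	0	0	0	0	0	1	0	1	0	0	0	1	0	0
Baibiandou	0	0	1	0	0	0	1	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0
Maidong	1	0	0	0	0	0	1	0	1	0	0	0	0	1	0	1	0	0	0	0	1	0	0
Wuweizi	0	0	1	0	0	0	1	1	0	0	0	0	0	1	0	1	1	0	0	0	0	0	0
Guijia	1	0	0	0	0	0	1	0	0	1	0	0	1	1	0	0	1	0	0	0	0	0	0
Huangbo	1	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0
Zhimu	1	0	0	0	0	0	1	0	1	0	0	0	0	0	0	1	1	0	0	0	1	0	0
Shanzhuyu	0	0	1	0	0	0	0	1	0	0	0	1	1	0	0	0	1	0	0	0	0	0	0
Roucongrong	0	0	1	0	0	0	1	0	0	1	0	0	0	0	0	0	1	0	1	0	0	0	0
Bajitian	0	0	1	0	0	1	1	0	0	0	0	0	1	0	0	0	1	0	0	0	0	0	0
Yuanzhi	0	0	1	0	0	1	0	0	1	0	0	0	0	1	0	1	1	0	0	0	0	0	0
Fuzi	0	1	0	0	0	1	1	0	0	0	0	0	0	1	1	0	1	0	0	0	0	0	0
Shihu	1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	1	0	0	0	1	0	0
Shichangpu	0	0	1	0	0	1	0	0	1	0	0	0	0	1	0	0	0	0	0	0	1	0	0
Rougui	0	1	0	0	0	1	1	0	0	0	0	0	1	1	1	0	1	0	0	0	0	0	0
Bohe	0	0	0	1	0	1	0	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0
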