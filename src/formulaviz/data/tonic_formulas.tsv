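formula	herb	is_principal
Bazhentang	Renshen	1
Bazhentang	Shudihuang	1
Bazhentang	Danggui	0
Bazhentang	Chuanxiong	0
Bazhentang	Baizhu	0
Bazhentang	Fuling	0
Bazhentang	Baishao	0
Bazhentang	Zhigancao	0
Bazhentang	Shengjiang	0
Bazhentang	Dazao	0
Shenlingbaizhusan	Renshen	1
Shenlingbaizhusan	Baizhu	1
Shenlingbaizhusan	Fuling	1
Shenlingbaizhusan	Lianzi	0
Shenlingbaizhusan	Yiyiren	0
Shenlingbaizhusan	Shanyao	0
Shenlingbaizhusan	Jiegeng	0
Shenlingbaizhusan	Dazao	0
Shenlingbaizhusan	Gancao	0
Shenlingbaizhusan	Sharen	0
Shenlingbaizhusan	Baibiandou	0
Shengmaisan	Renshen	1
Shengmaisan	Maidong	0
Shengmaisan	Wuweizi	0
Sijunzitang	Renshen	1
Sijunzitang	Gancao	0
Sijunzitang	Baizhu	0
Sijunzitang	Fuling	0
Dabuyinwan	Shudihuang	1
Dabuyinwan	Guijia	1
Dabuyinwan	Huangbo	0
Dabuyinwan	Zhimu	0
Siwutang	Shudihuang	1
Siwutang	Baishao	0
Siwutang	Chuanxiong	0
Siwutang	Danggui	0
Dihuangyinzi	Shudihuang	1
Dihuangyinzi	Shanzhuyu	1
Dihuangyinzi	Roucongrong	1
Dihuangyinzi	Bajitian	1
Dihuangyinzi	Maidong	0
Dihuangyinzi	Yuanzhi	0
Dihuangyinzi	Shengjiang	0
Dihuangyinzi	Fuzi	0
Dihuangyinzi	Fuling	0
Dihuangyinzi	Dazao	0
Dihuangyinzi	Wuweizi	0
Dihuangyinzi	Shihu	0
Dihuangyinzi	Shichangpu	0
Dihuangyinzi	Rougui	0
Dihuangyinzi	Bohe	0
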