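0 31
Beijing 2
Tianjin	Hebei
Tianjin 2
Beijing	Hebei
Hebei 7
Beijing	Tianjin	Shanxi	Inner Mongolia	Liaoning	Shandong	Henan
Shanxi 4
Hebei	Inner Mongolia	Henan	Shaanxi
Inner Mongolia 8
Hebei	Shanxi	Liaoning	Jilin	Heilongjiang	Shaanxi	Gansu	Ningxia
Liaoning 3
Hebei	Inner Mongolia	Jilin
Jilin 3
Inner Mongolia	Liaoning	Heilongjiang
Heilongjiang 2
Inner Mongolia	Jilin
Shanghai 2
Jiangsu	Zhejiang
Jiangsu 4
Shanghai	Zhejiang	Anhui	Shandong
Zhejiang 5
Shanghai	Jiangsu	Anhui	Fujian	Jiangxi
Anhui 6
Jiangsu	Zhejiang	Jiangxi	Shandong	Henan	Hubei
Fujian 3
Zhejiang	Jiangxi	Guangdong
Jiangxi 6
Zhejiang	Anhui	Fujian	Hubei	Hunan	Guangdong
Shandong 4
Hebei	Jiangsu	Anhui	Henan
Henan 6
Hebei	Shanxi	Anhui	Shandong	Hubei	Shaanxi
Hubei 6
Anhui	Jiangxi	Henan	Hunan	Chongqing	Shaanxi
Hunan 6
Jiangxi	Hubei	Guangdong	Guangxi	Chongqing	Guizhou
Guangdong 5
Fujian	Jiangxi	Hunan	Guangxi	Hainan
Guangxi 4
Hunan	Guangdong	Guizhou	Yunnan
Hainan 1
Guangdong
Chongqing 5
Hubei	Hunan	Sichuan	Guizhou	Shaanxi
Sichuan 7
Chongqing	Guizhou	Yunnan	Tibet	Shaanxi	Gansu	Qinghai
Guizhou 5
Hunan	Guangxi	Chongqing	Sichuan	Yunnan
Yunnan 4
Guangxi	Sichuan	Guizhou	Tibet
Tibet 4
Sichuan	Yunnan	Qinghai	Xinjiang
Shaanxi 8
Shanxi	Inner Mongolia	Henan	Hubei	Chongqing	Sichuan	Gansu	Ningxia
Gansu 6
Inner Mongolia	Sichuan	Shaanxi	Qinghai	Ningxia	Xinjiang
Qinghai 4
Sichuan	Tibet	Gansu	Xinjiang
Ningxia 3
Inner Mongolia	Shaanxi	Gansu
Xinjiang 3
Tibet	Gansu	Qinghai
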