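surface,label,source
兵庫県,ja_pref,address
京都府,ja_pref,address
大阪府,ja_pref,address
奈良県,ja_pref,address
鳥取県,ja_pref,address
岡山県,ja_pref,address
広島県,ja_pref,address
愛媛県,ja_pref,address
高知県,ja_pref,address
北海道,ja_pref,address
長野県,ja_pref,address
静岡県,ja_pref,address
三田市,ja_city,address
神戸市,ja_city,address
姫路市,ja_city,address
豊岡市,ja_city,address
丹波篠山市,ja_city,address
宝塚市,ja_city,address
京都市,ja_city,address
長岡京市,ja_city,address
松山市,ja_city,address
倉敷市,ja_city,address
松本市,ja_city,address
朝来市,ja_city,address
弥生が丘6丁目,ja_addr,address
下鴨本町19-1,ja_addr,address
六甲山町中一里山,ja_addr,address
藍本字山田,ja_addr,address
大河内町上岩,ja_addr,address
出石町宮内,ja_addr,address
上高地明神池畔,ja_addr,address
大山寺参道沿い,ja_addr,address
Hyogo Pref.,en_pref,address
Kyoto Pref.,en_pref,address
Osaka Pref.,en_pref,address
Nara Pref.,en_pref,address
Tottori Pref.,en_pref,address
Okayama Pref.,en_pref,address
Hiroshima Pref.,en_pref,address
Ehime Pref.,en_pref,address
Nagano Pref.,en_pref,address
Hokkaido,en_pref,address
Sanda-shi,en_city,address
Kobe City,en_city,address
Himeji City,en_city,address
Toyooka-shi,en_city,address
Takarazuka City,en_city,address
Kyoto City,en_city,address
Matsuyama City,en_city,address
Kurashiki City,en_city,address
Matsumoto City,en_city,address
Mt. Rokko,en_addr,address
Yayoigaoka 6 chome,en_addr,address
along Kamo River,en_addr,address
Mt. Daisen trail,en_addr,address
Kamikochi near Myojin Pond,en_addr,address
foot of Mt. Yukihiko,en_addr,address
Japan,country,address
日本,country,address
Nippon,country,address
JAPAN,country,address
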