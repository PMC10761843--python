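Takahashi, K.
Yamada, T.
S. Sato
M. Kobayashi
Suzuki, H.
Watanabe, A.
N. Fukuoka
J. Murata
Ito, R.
Y. Ibaragi
Nakamura, S.
田中 太郎
佐藤 健
伊藤 花子
小林 実
高橋 誠
山本 奈緒
加藤 隆
松本 和子
清水 修
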