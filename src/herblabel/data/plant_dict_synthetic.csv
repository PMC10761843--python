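surface,label,source
Lamiaceae,en_family_name,plant
Rosaceae,en_family_name,plant
Asteraceae,en_family_name,plant
Fagaceae,en_family_name,plant
Ericaceae,en_family_name,plant
Poaceae,en_family_name,plant
Cyperaceae,en_family_name,plant
Ranunculaceae,en_family_name,plant
Orchidaceae,en_family_name,plant
Polygonaceae,en_family_name,plant
Violaceae,en_family_name,plant
Araceae,en_family_name,plant
シソ科,jp_family_name,plant
バラ科,jp_family_name,plant
キク科,jp_family_name,plant
ブナ科,jp_family_name,plant
ツツジ科,jp_family_name,plant
イネ科,jp_family_name,plant
カヤツリグサ科,jp_family_name,plant
キンポウゲ科,jp_family_name,plant
ラン科,jp_family_name,plant
タデ科,jp_family_name,plant
スミレ科,jp_family_name,plant
サトイモ科,jp_family_name,plant
Salvia japonica,en_name,plant
Salvia japonica Thunb.,en_name,plant
Prunus jamasakura,en_name,plant
Quercus serrata,en_name,plant
Carex dissitiflora,en_name,plant
Isodon inflexus,en_name,plant
Clinopodium gracile,en_name,plant
Persicaria thunbergii,en_name,plant
Vaccinium hirtum,en_name,plant
Cirsium japonicum,en_name,plant
Miscanthus sinensis,en_name,plant
Arisaema serratum,en_name,plant
Viola grypoceras,en_name,plant
Rhododendron kaempferi,en_name,plant
Castanopsis sieboldii,en_name,plant
Ainsliaea apiculata,en_name,plant
Cymbidium goeringii,en_name,plant
Ranunculus japonicus,en_name,plant
Spiranthes sinensis,en_name,plant
Artemisia indica,en_name,plant
アキノタムラソウ,jp_name,plant
ヤマザクラ,jp_name,plant
コナラ,jp_name,plant
ミヤマカンスゲ,jp_name,plant
ヤマハッカ,jp_name,plant
トウバナ,jp_name,plant
ミゾソバ,jp_name,plant
ウスノキ,jp_name,plant
ノアザミ,jp_name,plant
ススキ,jp_name,plant
マムシグサ,jp_name,plant
タチツボスミレ,jp_name,plant
ヤマツツジ,jp_name,plant
スダジイ,jp_name,plant
キッコウハグマ,jp_name,plant
シュンラン,jp_name,plant
ウマノアシガタ,jp_name,plant
ネジバナ,jp_name,plant
ヨモギ,jp_name,plant
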