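site_name,site_id,chrono_group,mni_excl_fish,nisp_total,nisp_amphibians,nisp_birds,nisp_crustaceans,nisp_fish,nisp_mammals,nisp_marine_mammals,nisp_reptiles
Annas Minde II,MLF01352,Late Neolithic,15,352,0,4,0,5,343,0,0
Annas Minde III,MLF01353,Bronze Age,19,409,0,0,0,6,403,0,0
Annasminde IV,MLF01354,Bronze Age,28,2216,8,1,0,1469,736,0,2
Annasminde V,MLF01355,Bronze Age,17,274,0,0,0,7,265,2,0
Finlandsvej II,MLF02548,Bronze Age,13,120,2,0,0,7,111,0,0
Gokartbane,MLF01333,Middle Neolithic,5,706,0,0,0,615,91,0,0
RGS90,MLF00952,Bronze Age,9,50,0,0,0,0,50,0,0
Strandholm I,MLF00909,Late Neolithic,30,251,0,15,0,10,221,5,0
Strandholm V,MLF01182,Middle Neolithic,7,24,0,0,0,0,22,2,0
Strandholm VI,MLF01232-I,Bronze Age,50,763,0,0,0,733,30,0,0
Syltholm II,MLF00906,Late Mesolithic/Early Neolithic,151,2768,2,173,1,1007,1557,27,1
Syltholm IX,MLF00935,Middle Neolithic,47,372,1,11,0,99,257,4,0
Syltholm V,MLF00910,Late Mesolithic/Early Neolithic,3,24,0,0,0,20,4,0,0
Syltholm VII,MLF00933,Middle Neolithic,11,78,0,1,0,24,53,0,0
Syltholm X,MLF00936,Late Mesolithic/Early Neolithic,21,168,1,21,0,27,101,18,0
Syltholm XIII,MLF00939,Late Mesolithic/Early Neolithic,32,110,4,38,1,19,33,15,0
Syltholm XIV,MLF00940,Middle Neolithic,14,82,0,2,0,2,78,0,0
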