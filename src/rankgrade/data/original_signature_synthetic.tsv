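probe_id	direction
SYN200381_at	G3up
SYN201051_s_at	G3up
SYN201154_at	G3up
SYN201219_at	G3up
SYN201355_at	G3up
SYN201375_s_at	G3up
SYN201405_x_at	G3up
SYN201586_x_at	G3up
SYN201875_s_at	G3up
SYN202216_s_at	G3up
SYN202304_at	G3up
SYN203206_x_at	G3up
SYN203440_x_at	G3up
SYN203988_s_at	G3up
SYN204221_at	G3up
SYN204574_at	G3up
SYN204774_s_at	G3up
SYN205280_at	G3up
SYN205292_x_at	G3up
SYN205552_at	G3up
SYN206049_at	G3up
SYN206166_at	G3up
SYN206180_x_at	G3up
SYN206479_at	G3up
SYN206556_at	G3up
SYN206632_at	G3up
SYN206704_s_at	G3up
SYN207303_x_at	G3up
SYN207392_at	G3up
SYN208038_at	G3up
SYN208163_s_at	G3up
SYN208786_s_at	G3up
SYN209183_x_at	G3up
SYN210354_x_at	G3up
SYN210417_at	G3up
SYN210650_s_at	G3up
SYN210794_s_at	G3up
SYN210938_s_at	G3up
SYN211094_at	G3up
SYN211169_s_at	G3up
SYN211452_x_at	G3up
SYN211468_at	G3up
SYN211597_x_at	G3up
SYN211763_s_at	G3up
SYN211864_x_at	G3up
SYN212104_s_at	G3up
SYN212344_x_at	G3up
SYN212766_s_at	G3up
SYN213097_x_at	G3up
SYN213719_at	G3up
SYN213824_at	G3up
SYN213906_s_at	G3up
SYN214104_s_at	G3up
SYN214228_s_at	G3up
SYN215177_s_at	G3up
SYN215192_x_at	G3up
SYN215248_s_at	G3up
SYN215335_x_at	G3up
SYN216327_at	G3up
SYN216349_at	G3up
SYN216956_at	G3up
SYN216956_s_at	G3up
SYN217188_s_at	G3up
SYN217196_x_at	G3up
SYN217226_at	G3up
SYN217387_s_at	G3up
SYN218683_at	G3up
SYN218752_s_at	G3up
SYN218930_x_at	G3up
SYN219674_s_at	G3up
SYN219808_s_at	G3up
SYN220073_at	G3up
SYN220256_s_at	G3up
SYN220287_s_at	G3up
SYN220517_x_at	G3up
SYN220616_x_at	G3up
SYN220688_x_at	G3up
SYN220728_at	G3up
SYN220880_x_at	G3up
SYN220972_s_at	G3up
SYN221048_s_at	G3up
SYN221111_s_at	G3up
SYN221364_at	G3up
SYN221503_at	G3up
SYN221519_s_at	G3up
SYN221703_s_at	G3up
SYN222139_at	G3up
SYN222142_at	G3up
SYN222552_at	G3up
SYN222697_s_at	G3up
SYN222905_s_at	G3up
SYN223517_at	G3up
SYN224058_s_at	G3up
SYN224481_x_at	G3up
SYN224697_s_at	G3up
SYN225416_s_at	G3up
SYN225543_at	G3up
SYN225704_x_at	G3up
SYN225769_x_at	G3up
SYN226736_s_at	G3up
SYN226779_at	G3up
SYN227186_x_at	G3up
SYN227354_s_at	G3up
SYN227570_at	G3up
SYN227682_at	G3up
SYN227882_at	G3up
SYN228065_x_at	G3up
SYN228334_x_at	G3up
SYN228460_x_at	G3up
SYN228554_x_at	G3up
SYN228679_s_at	G3up
SYN229847_x_at	G3up
SYN200134_at	G1up
SYN200791_x_at	G1up
SYN201120_at	G1up
SYN205512_s_at	G1up
SYN206922_x_at	G1up
SYN208715_s_at	G1up
SYN214499_x_at	G1up
SYN216579_at	G1up
SYN218563_at	G1up
SYN218791_at	G1up
SYN221596_s_at	G1up
SYN224511_at	G1up
SYN224525_s_at	G1up
SYN225448_x_at	G1up
SYN225656_at	G1up
SYN225830_x_at	G1up
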