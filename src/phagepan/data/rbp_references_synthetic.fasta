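>rbpref_I synthetic RBP group I reference
MNRYEANFEQTLVHFTHVVLVFRPNGNYYFNNQWGFCQSTRGAHAYCCDARHDSQNEFTPGDCHCRVKFH
GSIFNFPMDIVTKCDGKHQANICEKSQHKPHDQHEHMEHRCLIVDWIKDIIHINCVCAYHTPYSARTVHS
MGGWRNTDICANTFMYCWSNKRNFSSQYCPFDMCHTNICVASWPKHKNEKCQWELSSDIAGDTDLPHLEQ
YLPRIRFWVTRDCPWRKMVDGMVFEMFFQCCKGYDSSSGTRNGFSCHW
>rbpref_II synthetic RBP group II reference
MGCPNRFQHTKLMKLEAYIKEQMYTFWWHVIRVYNMGWDITGRCDKEMWLPTEWNPSMCCAWWSWNTNPS
KFVDYHGRQELPFHPSNCFLEWPKDCRTQGLHHGCPMWDVPKWKKWFHFRWSKATFSHRGDTGRMSYHAH
ELDVQCYWGLCKTMACQAKRKKECWPGLIYYSINFVPLPYNLSQPTTGHWEVRSHTVIPKWKNGCSMTFW
KTMQWPSKIDRDAEFMQYKTPMSDALVKYPIWCCGLALDWCRCVYMIRAGWHHSECFQ
>rbpref_III synthetic RBP group III reference
MACNLVDDFCMFYIWLPYTCGSRAHRTQDPANHIPNMCRCAEVWEANTQYRVFVHRDCVECYAEKYPGLC
QYNVQCSCLVKYYMLLTIKHSSSDKFDAWLDFEPIFQDTDVQTHTAYVQFENHTRAQATMIPLIDFPYAH
SCVMYPQDRMHMLFVYPNLCIKMLEYSFLNGYSKSPQDMWPHSEKHGSDCNLHTRRSVCIWGDWPCMNTK
YCQHMGGTGNPVNWRRLNGRWHKSWPQLSFHGCNKYICEGNMAD
>rbpref_IV synthetic RBP group IV reference
MYNHCFAWVGDKAMLQSWDWNVYQHVAWSDKAGDHWWLVVREMGPDWKNIVFVQMEYVQSMNSFNEAGYA
VGKKLNSFKEYHWYTEHCCNTPLSHTSFIKNFFGQHHHVMYFKTYERITLQADCMYYFHPAMGFLWWGTW
QMKKDHQDLEVPHGQWLSMEIFNPQFGKTPMKIAIDSLEWWMAPGIVMCFDKDEKFSYLMDKLVNYFGIG
TTEGIIWWTQLYICYYVGNPGNAVSDPLFAETSILTGDIVRPAEPYE
>rbpref_V synthetic RBP group V reference
MVYKDNELESDAQTPTEFSWTFDDRNTDGGDGYMTGWHSFAANSGDELRKYRRPVFHRYAVVAKIHPPYK
LDVQGLNWRPCCPQAFLASIRQVQSNPDAATSHPAYDCSHIANWICFANGVLVSLKTDSHHLWEIHHAHE
MPQYEPLYCKFTNEWWWGNERVMVKDPVVWVMQTLYSKFCYVHCCCCWSHQVDECIPVCGTPLRGLYQVE
CINHIVMCSHQNNGHSICKHIDKVNPFTVSHHMRICRQLQFLDQPMKCFHRKSHLMDF
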